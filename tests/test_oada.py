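"""OADA partial likelihood, fitting, model comparison and averaging."""

import itertools
import math

import numpy as np
import pytest

from socdiff import (
    AssociationMatrix,
    DiffusionLog,
    ModelTable,
    OADAFit,
    OADASpec,
    aicc,
    compare_networks,
    diffusion_loglik,
    fit_oada,
    model_average,
    s_bounded_from_unbounded,
    s_unbounded_from_bounded,
    transmission_term,
)
from socdiff.records import PhenotypeRecord, phenotype_frame


def _matrix(ids, w, directed=False, rule="ten_m"):
    return AssociationMatrix("T", rule, tuple(ids), np.asarray(w, float), directed)


def _phen(ids, troop="T"):
    recs = [
        PhenotypeRecord(i, troop, "male" if k % 2 else "female",
                        3.0 + 2 * k, k + 1, 4.0 * k)
        for k, i in enumerate(ids)
    ]
    return phenotype_frame(recs)


@pytest.fixture
def undirected5():
    rng = np.random.default_rng(7)
    w = rng.random((5, 5))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    return _matrix("ABCDE", w)


class TestTransmissionTerm:
    def test_no_informed_neighbours_zero(self, undirected5):
        assert transmission_term("A", set(), undirected5) == 0.0

    def test_undirected_sum(self):
        m = _matrix("ABC", [[0, 0.5, 0.25], [0.5, 0, 0], [0.25, 0, 0]])
        assert transmission_term("A", {"B", "C"}, m) == pytest.approx(0.75)

    def test_directed_outgoing_vs_incoming(self):
        m = _matrix("AB", [[0, 2], [1, 0]], directed=True, rule="groom_directed")
        assert transmission_term("A", {"B"}, m, direction="outgoing") == 2
        assert transmission_term("A", {"B"}, m, direction="incoming") == 1

    def test_fully_informed_complete_graph(self):
        n = 4
        w = np.ones((n, n)) - np.eye(n)
        m = _matrix("ABCD", w)
        assert transmission_term("A", {"B", "C", "D"}, m) == n - 1


class TestLikelihood:
    def test_asocial_uniform_order_probability(self, tiny_phen):
        # 3 naive individuals acquiring in a full order: probability 1/3!
        log = DiffusionLog("t", "T", "A",
                           acquisition_events=[{"B"}, {"C"}, {"D"}])
        spec = OADASpec(None, "asocial", ())
        phen = tiny_phen[tiny_phen.individual_id.isin(list("ABCD"))]
        ll = diffusion_loglik(log, None, spec, phen)
        assert ll == pytest.approx(math.log(1 / 6))

    def test_order_probabilities_normalize(self, undirected5, tiny_phen):
        betas = {"rank": 0.4, "age": -0.1}
        for spec in [
            OADASpec("ten_m", "additive", ("rank", "age")),
            OADASpec("ten_m", "multiplicative", ("rank",)),
        ]:
            total = 0.0
            for order in itertools.permutations("BCDE"):
                log = DiffusionLog("t", "T", "A",
                                   acquisition_events=[frozenset([x]) for x in order])
                total += math.exp(
                    diffusion_loglik(log, undirected5, spec, tiny_phen, s=1.7, betas=betas)
                )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_additive_equals_multiplicative_without_ilvs(self, undirected5, tiny_phen):
        log = DiffusionLog("t", "T", "A", acquisition_events=[{"C"}, {"B", "E"}])
        for s in (0.0, 0.5, 3.0, 50.0):
            la = diffusion_loglik(log, undirected5, OADASpec("ten_m", "additive", ()),
                                  tiny_phen, s=s)
            lm = diffusion_loglik(log, undirected5, OADASpec("ten_m", "multiplicative", ()),
                                  tiny_phen, s=s)
            assert la == pytest.approx(lm, abs=1e-12)

    def test_s_zero_reduces_to_asocial(self, undirected5, tiny_phen):
        log = DiffusionLog("t", "T", "A", acquisition_events=[{"B"}, {"D"}])
        betas = {"rank": 0.8, "sex": -0.2}
        base = diffusion_loglik(log, None, OADASpec(None, "asocial", ("rank", "sex")),
                                tiny_phen, betas=betas)
        for form in ("additive", "multiplicative"):
            social = diffusion_loglik(
                log, undirected5, OADASpec("ten_m", form, ("rank", "sex")),
                tiny_phen, s=0.0, betas=betas,
            )
            assert social == base

    def test_breslow_equals_exact_without_ties(self, undirected5, tiny_phen):
        log = DiffusionLog("t", "T", "A",
                           acquisition_events=[{"B"}, {"C"}, {"D"}, {"E"}])
        for method in ("breslow", "exact"):
            ll = diffusion_loglik(
                log, undirected5,
                OADASpec("ten_m", "additive", ("rank",), tie_method=method),
                tiny_phen, s=2.0, betas={"rank": 0.3},
            )
            if method == "breslow":
                ref = ll
        # identical up to float summation order of the two code paths
        assert ll == pytest.approx(ref, abs=1e-12)

    def test_exact_tie_is_average_over_orderings(self, undirected5, tiny_phen):
        # tied acquirers are simultaneous: rates stay at the pre-event
        # state, and the exact method averages the shrinking-denominator
        # sequential probabilities over the tie's orderings
        tied = DiffusionLog("t", "T", "A", acquisition_events=[{"B", "C"}, {"D"}])
        spec = OADASpec("ten_m", "additive", (), tie_method="exact")
        s = 1.3
        ll = diffusion_loglik(tied, undirected5, spec, tiny_phen, s=s)

        def rate(i, informed):
            return s * transmission_term(i, informed, undirected5) + 1.0

        r = {i: rate(i, {"A"}) for i in "BCDE"}
        d0 = sum(r.values())
        p_tie = 0.5 * (
            r["B"] / d0 * r["C"] / (d0 - r["B"]) + r["C"] / d0 * r["B"] / (d0 - r["C"])
        )
        r2 = {i: rate(i, {"A", "B", "C"}) for i in "DE"}
        expected = math.log(p_tie * r2["D"] / (r2["D"] + r2["E"]))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_empty_risk_set_is_integrity_error(self, tiny_phen):
        from socdiff.oada import OADAError

        ids = ("A", "B")
        m = _matrix(ids, [[0, 1], [1, 0]])
        phen = tiny_phen[tiny_phen.individual_id.isin(ids)]
        log = DiffusionLog("t", "T", "A", acquisition_events=[{"B"}, {"C"}])
        with pytest.raises(OADAError):
            diffusion_loglik(log, m, OADASpec("ten_m", "additive", ()), phen, s=1.0)


class TestParameterScales:
    def test_bounded_unbounded_bijection(self):
        for s in (0.0, 0.1, 1.0, 9.0, 999.0):
            assert s_unbounded_from_bounded(s_bounded_from_unbounded(s)) == pytest.approx(s)
        vals = [s_bounded_from_unbounded(s) for s in (0.0, 0.5, 1.0, 5.0, 100.0)]
        assert vals == sorted(vals)
        assert vals[0] == 0.0 and vals[-1] < 1.0

    def test_aicc_identity_and_limit(self):
        ll, k = -512.3, 5
        assert aicc(ll, k, 100) == pytest.approx(
            -2 * ll + 2 * k + 2 * k * (k + 1) / (100 - k - 1)
        )
        assert aicc(ll, k, 10**9) == pytest.approx(-2 * ll + 2 * k, abs=1e-3)
        assert math.isinf(aicc(ll, 5, 6))


class TestFitting:
    def test_asocial_data_fits_s_near_zero(self, small_study):
        """Nested-model boundary: diffusions simulated without social
        transmission recover s ~ 0 and the asocial log-likelihood."""
        from socdiff import SimScenario, simulate_study

        sc = SimScenario(seed=5, troop_sizes=(14,), n_diffusions_per_troop=12,
                         s_bounded_true=0.0, tie_rate=0.0, unknown_rate=0.0,
                         ilv_betas_true={})
        study = simulate_study(sc)
        spec = OADASpec("ten_m", "additive", ())
        fit = fit_oada(study.diffusions, study.networks_by_rule()["ten_m"],
                       spec, study.phenotypes)
        asocial = fit_oada(study.diffusions, None, OADASpec(None, "asocial", ()),
                           study.phenotypes)
        assert fit.s_bounded < 0.2
        assert fit.loglik >= asocial.loglik - 1e-9
        assert fit.loglik <= asocial.loglik + 2.0  # boundary gain is small

    def test_nested_ilv_never_decreases_loglik(self, small_study):
        by_rule = small_study.networks_by_rule()["ten_m"]
        lls = {}
        for ilvs in [(), ("rank",), ("rank", "sex")]:
            fit = fit_oada(small_study.diffusions, by_rule,
                           OADASpec("ten_m", "multiplicative", ilvs),
                           small_study.phenotypes)
            lls[ilvs] = fit.loglik
        assert lls[("rank",)] >= lls[()] - 1e-6
        assert lls[("rank", "sex")] >= lls[("rank",)] - 1e-6

    def test_duplicate_candidate_matrices_give_identical_rows(self, small_study):
        by_rule = small_study.networks_by_rule()
        nets = {"ten_m": by_rule["ten_m"], "copy": by_rule["ten_m"]}
        table = compare_networks(small_study.diffusions, nets, small_study.phenotypes,
                                 forms=("additive",), ilvs=())
        df = table.frame()
        a = df[df.network == "ten_m"].iloc[0]
        b = df[df.network == "copy"].iloc[0]
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)
        assert a.aicc == pytest.approx(b.aicc, abs=1e-9)

    def test_model_table_invariants(self, small_study):
        by_rule = small_study.networks_by_rule()
        nets = {r: by_rule[r] for r in ("ten_m", "groom_directed")}
        df = compare_networks(small_study.diffusions, nets, small_study.phenotypes,
                              forms=("additive", "multiplicative"), ilvs=("rank",)).frame()
        assert (df.delta_aicc >= 0).all()
        assert (df.delta_aicc == 0).sum() >= 1
        assert df.akaike_weight.sum() == pytest.approx(1.0)


class TestModelAverage:
    def _fit(self, ilvs, betas, loglik, n=200):
        spec = OADASpec("ten_m", "multiplicative", ilvs)
        return OADAFit(spec=spec, s_unbounded=1.0, betas=betas,
                       loglik=loglik, k=spec.k, n_events=n)

    def test_single_model_unchanged(self):
        table = ModelTable(fits=[self._fit(("rank",), {"rank": 0.37}, -100.0)])
        assert model_average(table) == {"rank": pytest.approx(0.37)}

    def test_zero_substitution_with_equal_weights(self):
        # two equally supported models; 'rank' absent from the second
        f1 = self._fit(("rank",), {"rank": 0.4}, -100.0)
        # pick the second model's loglik so its AICc matches despite smaller k
        f2 = self._fit((), {}, 0.0)
        f2.loglik = -(f1.aicc - 2 * f2.k - 2 * f2.k * (f2.k + 1) / (f2.n_events - f2.k - 1)) / 2
        assert f2.aicc == pytest.approx(f1.aicc)
        table = ModelTable(fits=[f1, f2])
        assert model_average(table)["rank"] == pytest.approx(0.2)

    def test_distant_models_excluded(self):
        f1 = self._fit(("rank",), {"rank": 0.4}, -100.0)
        f2 = self._fit(("rank",), {"rank": 5.0}, -150.0)
        assert model_average(table=ModelTable(fits=[f1, f2]))["rank"] == pytest.approx(0.4)
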