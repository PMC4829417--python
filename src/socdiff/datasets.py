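"""Small reference datasets built programmatically.

`reference_study_logs` reconstructs the summary-level structure of the
published two-troop field experiment that this package's methods were
designed around: 50 successful diffusion experiments of which 44 have
extractable patch-entry data totalling 293 entries, 14 of them
co-feeding (5 with vocal protest), and discoverers located at the
troop's leading edge in 28 experiments, side periphery in 11 and
middle-back in 11.  Individual identities and acquisition orders are
synthetic placeholders — only the tallied quantities are faithful to
the published summary.
"""

from __future__ import annotations

from .records import ApplicationEvent, DiffusionLog

N_EXPERIMENTS = 50
N_WITH_ENTRY_DATA = 44
N_ENTRIES = 293
N_COFEED = 14
N_PROTESTED = 5
N_LEADING_EDGE = 28
N_SIDE = 11
N_MIDDLE_BACK = 11


def reference_study_logs() -> list[DiffusionLog]:
    """Deterministically build the 50 reference diffusion logs."""
    positions = (
        ["leading_edge"] * N_LEADING_EDGE + ["side"] * N_SIDE + ["middle_back"] * N_MIDDLE_BACK
    )
    base, extra = divmod(N_ENTRIES, N_WITH_ENTRY_DATA)
    sizes = [base + 1 if k < extra else base for k in range(N_WITH_ENTRY_DATA)]
    sizes += [0] * (N_EXPERIMENTS - N_WITH_ENTRY_DATA)

    logs: list[DiffusionLog] = []
    cofeed_left, protest_left = N_COFEED, N_PROTESTED
    for k in range(N_EXPERIMENTS):
        troop = "J" if k % 2 == 0 else "L"
        discoverer = f"X{k:02d}D"
        applicants = [f"X{k:02d}A{j}" for j in range(sizes[k])]
        apps = []
        for j, ind in enumerate(applicants):
            cofeed = j == 0 and cofeed_left > 0
            protested = cofeed and protest_left > 0
            if cofeed:
                cofeed_left -= 1
            if protested:
                protest_left -= 1
            apps.append(
                ApplicationEvent(individual_id=ind, fed=(j % 2 == 0),
                                 cofeed=cofeed, protested=protested)
            )
        logs.append(
            DiffusionLog(
                task_id=f"ref-{k:02d}",
                troop_id=troop,
                discoverer_id=discoverer,
                acquisition_events=[frozenset([ind]) for ind in applicants],
                application_events=apps,
                discovery_position=positions[k],
            )
        )
    return logs
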