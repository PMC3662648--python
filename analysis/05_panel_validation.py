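"""Validation-panel statistics and the small-pool ascertainment analysis.

Simulates a 17-locus genotyping panel (10/11 individuals per elevation in
the discovery population, 11/10 in an independent one), computes Ho/He and
exact HWE per locus and group with Holm correction, runs the pairwise LD
permutation test within groups, and tabulates the apparent-fixation
probability (1-q)^6 + q^6 for a pool of three diploids against simulation,
with and without read-depth conditioning.
"""

from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from pikapool.popgen import (
    apparent_fixation_probability,
    ld_permutation_test,
    panel_statistics,
    simulate_apparent_fixation,
)
from pikapool.simulate import simulate_validation_panel

SEED = 0
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    panel = simulate_validation_panel(seed=SEED)
    stats = panel_statistics(panel)
    stats.to_csv(RESULTS / "panel_statistics.tsv", sep="\t", index=False)
    n_mono = int(stats["monomorphic"].sum())
    n_hwe = int(stats["hwe_reject_holm"].sum())
    print(f"{len(stats)} locus-group cells; {n_mono} monomorphic; "
          f"{n_hwe} HWE rejections after Holm correction")

    # pairwise LD within each group (only polymorphic locus pairs are testable)
    ld_rows = []
    for (site, elev), grp in panel.groupby(["site", "elevation"]):
        wide = grp.pivot(index="individual", columns="locus", values="genotype")
        for a, b in combinations(wide.columns, 2):
            res = ld_permutation_test(
                wide[a].to_numpy(), wide[b].to_numpy(), n_permutations=199, seed=SEED
            )
            if res.testable:
                ld_rows.append(
                    {"site": site, "elevation": elev, "locus_a": a, "locus_b": b,
                     "G": round(res.statistic, 3), "p": res.p_value}
                )
    ld = pd.DataFrame(ld_rows)
    ld.to_csv(RESULTS / "ld_tests.tsv", sep="\t", index=False)
    from pikapool.popgen import holm_correction

    n_ld_sig = int(holm_correction(ld["p"].to_numpy(), alpha=0.05).sum()) if len(ld) else 0
    print(f"{len(ld)} testable LD pairs; {n_ld_sig} significant after Holm "
          "(loci are simulated independently, so ~0 expected)")

    # ascertainment: apparent fixation in a pool of 3 diploids
    rows = []
    for q in (0.02, 0.05, 0.10, 0.20, 0.30, 0.50):
        closed = apparent_fixation_probability(q, 3)
        sim = simulate_apparent_fixation(q, 3, n_sites=20_000, seed=SEED)
        sim_depth = simulate_apparent_fixation(q, 3, n_sites=20_000, seed=SEED, depth=30)
        rows.append(
            {"q": q, "closed_form": round(closed, 6),
             "simulated": round(sim, 4), "simulated_depth30": round(sim_depth, 4)}
        )
    fixation = pd.DataFrame(rows)
    fixation.to_csv(RESULTS / "apparent_fixation.tsv", sep="\t", index=False)
    print(fixation.to_string(index=False))
    print(
        "a site at q = 0.10 looks fixed in a 3-diploid pool more than half the "
        "time (0.531); finite 30x read depth inflates this further - the "
        "mechanism that inflates fixed-site categories in small-pool discovery"
    )


if __name__ == "__main__":
    main()
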