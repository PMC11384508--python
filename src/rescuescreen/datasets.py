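"""Synthetic reference screen standing in for the published screen results.

The screen this package scores was reported only as supplementary tables,
with no deposited sequencing reads, so no real count-level dataset exists to
run against. This module builds a fully SYNTHETIC stand-in with the screen's
documented design (950 targeted genes x 4 sgRNAs + 50 nontargeting controls,
biological quadruplicate, three arms) in which the validated genes are
spiked in with their reported qualitative outcomes:

* rescuing knockouts (guides enrich in the YAP arm): YAP1, TEAD1, TEAD4,
  ITGB5, RAB25, TGIF2, UNC5B, and SAP30 — SAP30 with exactly 3 of 4
  functional guides, matching its reported 3-of-4 enriched guides;
* sensitizing knockouts (guides deplete): NF2, AMOTL2, KIRREL, and MORC2 —
  MORC2 with all 4 guides functional, matching its reported 4-of-4 depleted
  guides.

The handful of published spacer sequences (two nontargeting controls, two
TEAD1 guides, two UNC5B guides) are used verbatim; every other spacer is a
random 20-mer. All counts are simulated — nothing here is measured data.
"""

from __future__ import annotations

import pandas as pd

from .quantify import CountMatrix, LibraryDesign
from .simulate import EFFECTOR, INHIBITOR, SimConfig, SimTruth, simulate_library, simulate_counts

#: Spacer sequences printed in the screen's validation experiments.
PUBLISHED_SPACERS: dict[str, str] = {
    "NTC_sg001": "GACCGGAACGATCTCGCGTA",   # sgControl #1
    "NTC_sg002": "CGCTTCCGCGGCCCGTTCAA",   # sgControl #2
    "TEAD1_sg1": "GGCCGGGAATGATTCAAACA",   # sgTEAD1-3415
    "TEAD1_sg2": "ACATGGTGGATAGATAGCCA",   # sgTEAD1-3418
    "UNC5B_sg1": "CCAGAACGACCACGTCACAC",   # sgUNC5B-3692
    "UNC5B_sg2": "ATACCCTAGCGATTTCGCCC",   # sgUNC5B-3693
}

RESCUE_GENES = ("YAP1", "TEAD1", "TEAD4", "ITGB5", "RAB25", "TGIF2", "UNC5B",
                "SAP30")
SENSITIZER_GENES = ("NF2", "AMOTL2", "KIRREL", "MORC2")


def reference_screen_config(seed: int = 0) -> SimConfig:
    """Default screen-design configuration of the synthetic reference."""
    return SimConfig(seed=seed)


def synthetic_reference_screen(
    seed: int = 0,
) -> tuple[LibraryDesign, SimTruth, CountMatrix]:
    """Simulate the synthetic reference screen (library, truth, counts)."""
    config = reference_screen_config(seed)
    known = list(RESCUE_GENES) + list(SENSITIZER_GENES)
    fillers = [f"G{i:04d}" for i in range(1, config.n_genes - len(known) + 1)]
    gene_names = known + fillers

    class_overrides = {g: EFFECTOR for g in RESCUE_GENES}
    class_overrides.update({g: INHIBITOR for g in SENSITIZER_GENES})
    active_overrides = {
        "SAP30": [True, True, True, False],  # 3 of 4 guides functional
        "MORC2": [True, True, True, True],   # 4 of 4 guides functional
        "TEAD1": [True, True, True, True],
        "UNC5B": [True, True, True, True],
        "YAP1": [True, True, True, True],
    }
    library, truth = simulate_library(
        config,
        gene_names=gene_names,
        class_overrides=class_overrides,
        active_overrides=active_overrides,
    )
    table = library.table.copy()
    lut = dict(zip(table["sgrna_id"], table.index))
    for sid, spacer in PUBLISHED_SPACERS.items():
        table.loc[lut[sid], "spacer"] = spacer
    library = LibraryDesign(table)  # revalidates uniqueness
    counts = simulate_counts(library, truth, config)
    return library, truth, counts
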