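"""Packaged study fixtures.

`load_table4_cohort` expands the published method-1 post-revision contingency
table (249 assessable ovarian-carcinoma cases: staining pattern x mutation
type) into one synthetic case row per count.  Cell totals are exact; the
per-case variant notations and the histotype assignment are synthetic
reconstructions chosen to be mechanistically typical of each cell (early
truncations in the complete-absence cell, the recurrent p.R306X stopgain in
the cytoplasmic cell, the recurrent in-frame p.I255del in the
overexpression/indel cell, and the published hotspot substitutions among the
missense cases).  The real per-case study table is not public, so nothing
here identifies actual cases.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import pandas as pd

__all__ = ["TABLE4_CELLS", "STUDY_DESIGN", "load_table4_cohort"]

#: Published contingency counts: staining pattern (rows) x mutation type (cols).
TABLE4_CELLS: Dict[str, Dict[str, int]] = {
    "OE": {"nonsynonymous": 115, "indel": 2, "stopgain": 2, "splicing": 2, "NDM": 0},
    "CA": {"nonsynonymous": 0, "indel": 16, "stopgain": 13, "splicing": 12, "NDM": 0},
    "CY": {"nonsynonymous": 0, "indel": 2, "stopgain": 2, "splicing": 0, "NDM": 0},
    "WT": {"nonsynonymous": 0, "indel": 4, "stopgain": 0, "splicing": 3, "NDM": 76},
}

#: Study-design cohort sizes and headline counts used for cohort fractions.
STUDY_DESIGN = {
    "n_hgsoc": 171,
    "n_ec": 80,
    "hgsoc_deleterious": 169,
    "ec_deleterious": 7,
}

_HOTSPOT_FILL = [
    "p.C176F", "p.H179R", "p.G245S", "p.R248Q", "p.R249S", "p.R282W",
    "p.V157F", "p.Y163C", "p.R158L", "p.S241F", "p.C238Y", "p.E285K",
    "p.L194R", "p.I195T", "p.V216M", "p.Y234C", "p.M237I", "p.G266E",
]


def _missense_variants(n: int) -> List[str]:
    out = ["p.R175H"] * 9 + ["p.Y220C"] * 6 + ["p.R273H"] * 5
    i = 0
    while len(out) < n:
        out.append(_HOTSPOT_FILL[i % len(_HOTSPOT_FILL)])
        i += 1
    return out[:n]


def _cycle(templates: List[str], n: int) -> List[str]:
    return [templates[i % len(templates)] for i in range(n)]


# Variant notations per (pattern, mutation-type) cell.  Truncations in the CA
# cells sit before codon 213 (NMD territory), WT-cell truncations after codon
# 245, and the CY-cell products fall in the 292-306 aa window.
_CELL_VARIANTS: Dict[Tuple[str, str], List[str]] = {
    ("OE", "nonsynonymous"): _missense_variants(115),
    ("OE", "indel"): ["p.I255del"] * 2,
    ("OE", "stopgain"): ["p.R342X", "p.E349X"],
    ("OE", "splicing"): ["c.993+1G>T", "c.994-1G>T"],
    ("CA", "indel"): _cycle(
        ["p.L45fs", "p.Q68fs", "p.S91fs", "p.P113fs", "p.T126fs", "p.K140fs",
         "p.P152fs", "p.H168fs", "p.R181fs", "p.P190fs"], 16
    ),
    ("CA", "stopgain"): ["p.R196X"] * 4 + [
        "p.E53X", "p.Q65X", "p.W83X", "p.Q104X", "p.K120X",
        "p.C136X", "p.W146X", "p.Q165X", "p.R209X",
    ],
    ("CA", "splicing"): ["c.356-2delA"] + [
        "c.97-1G>A", "c.375+1G>A", "c.376-1G>A", "c.559+1G>A", "c.560-1G>A",
        "c.672+1G>A", "c.673-1G>A", "c.782+1G>A", "c.783-1G>A", "c.919+1G>A",
        "c.920-1G>A",
    ],
    ("CY", "indel"): ["p.P295fs", "p.T304fs"],
    ("CY", "stopgain"): ["p.R306X", "p.R306X"],
    ("WT", "indel"): ["p.K382fs", "p.E343fs", "p.Q331fs", "p.P359fs"],
    ("WT", "splicing"): ["c.1100+1G>A", "c.1101-1G>A", "c.672+2T>C"],
    ("WT", "NDM"): ["NDM"] * 75 + ["p.R213R"],  # one synonymous change among NDM
}


def load_table4_cohort() -> pd.DataFrame:
    """The 249-case fixture cohort with method-1 staining calls.

    Histotype reconstruction: the endometrioid (EC) cases are 5 GOF
    (missense/OE), 2 LOF (CA/indel) and 73 NDM (including the synonymous
    change); all remaining cases are HGSOC.  This reproduces the published
    per-histotype counts of deleterious mutations (7 EC), WT-staining LOF
    HGSOC (7) and cytoplasmic HGSOC (4).
    """
    rows = []
    ec_quota = {("OE", "nonsynonymous"): 5, ("CA", "indel"): 2, ("WT", "NDM"): 73}
    for pattern, by_type in TABLE4_CELLS.items():
        for mtype, count in by_type.items():
            if count == 0:
                continue
            variants = _CELL_VARIANTS[(pattern, mtype)]
            assert len(variants) == count, (pattern, mtype)
            n_ec = ec_quota.get((pattern, mtype), 0)
            for i, variant in enumerate(variants):
                # EC cases fill the tail of the cell so hotspots stay HGSOC
                histotype = "EC" if i >= count - n_ec else "HGSOC"
                rows.append((histotype, variant, pattern))
    df = pd.DataFrame(rows, columns=["histotype", "variant", "pattern_m1"])
    df.insert(0, "case_id", [f"T{i + 1:03d}" for i in range(len(df))])
    return df
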