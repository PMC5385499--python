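"""Small reference datasets bundled with the package.

``SOLENOSMILIA_GENOTYPIC_COUNTS`` holds per-site sample counts (N) and
unique multilocus-genotype counts (Ng) for *Solenosmilia variabilis*
collected on Southern Ocean seamounts -- the worked example used
throughout the documentation for genotypic richness R = (G - 1)/(N - 1).
"""

from __future__ import annotations

import pandas as pd

from .clonality import genotypic_richness

# site, N (samples genotyped), Ng (unique multilocus genotypes)
SOLENOSMILIA_GENOTYPIC_COUNTS: list[tuple[str, int, int]] = [
    ("Dory Hill", 34, 20),
    ("Hill U 12", 37, 15),
    ("Hill U 13", 37, 22),
    ("Hill U 14", 39, 22),
    ("Hill U 15", 39, 19),
    ("Hill U 16", 22, 19),
    ("L Mongrel", 38, 20),
    ("Mac Ridge", 15, 10),
    ("MiniMatt33", 34, 16),
    ("MiniMatt34", 35, 26),
    ("MiniMatt35", 39, 15),
    ("MiniMatt36", 24, 14),
    ("MiniMatt37", 39, 30),
    ("Tasman1200", 34, 22),
    ("Z15", 34, 23),
    ("Z56", 37, 9),
    ("Z9", 43, 22),
]


def solenosmilia_genotypic_table() -> pd.DataFrame:
    """Genotypic-diversity table: N, Ng, Ng:N and richness R per site."""
    rows = []
    for site, n, g in SOLENOSMILIA_GENOTYPIC_COUNTS:
        rows.append(
            {
                "site": site,
                "N": n,
                "Ng": g,
                "Ng_N": g / n,
                "R": genotypic_richness(n, g),
            }
        )
    return pd.DataFrame(rows)
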