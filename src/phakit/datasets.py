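"""Published reference values used as fixed inputs.

``cobetia_productivity_table`` returns the printed harvest data for
*Cobetia* sp. MC34 and *C. marina* DSM 4741 grown on five carbon
substrates: OD600 at harvest, cell dry weight (g/L), monomer content
measured by GC-FID (% of CDW, 3HB and — where valerate was co-fed —
3HV), and the printed PHA titer (g/L).  These are measured wet-lab
values and enter the package only as inputs to the titer arithmetic and
its consistency checks; nothing here recomputes them.

Two rows (MC34 on acetate and DSM 4741 on glycerol) are known to be
inconsistent with arithmetic on the printed rounded inputs — the source
presumably rounded CDW and fractions after computing the titer — and
are flagged by the productivity report.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cobetia_productivity_table", "SELF_CONSISTENT_ROWS"]

_ROWS = [
    # strain, substrate, od_harvest, cdw, %3HB, %3HV, printed PHA g/L
    ("Cobetia sp. MC34", "acetate",            15.0, 3.4, 72.0, None, 2.5),
    ("Cobetia sp. MC34", "acetate+valerate",   14.2, 3.4, 48.0, 14.0, 2.1),
    ("Cobetia sp. MC34", "glycerol",            6.2, 2.5, 26.0, None, 0.7),
    ("Cobetia sp. MC34", "glucose",             6.5, 1.8, 35.0, None, 0.6),
    ("Cobetia sp. MC34", "fructose",            6.0, 3.9,  9.9, None, 0.4),
    ("C. marina DSM 4741", "acetate",          15.0, 3.9, 61.0, None, 2.4),
    ("C. marina DSM 4741", "acetate+valerate", 17.0, 4.4, 59.0, 26.0, 3.7),
    ("C. marina DSM 4741", "glycerol",         14.0, 4.0, 61.0, None, 2.5),
    ("C. marina DSM 4741", "glucose",           8.0, 2.4, 46.0, None, 1.1),
    ("C. marina DSM 4741", "fructose",          8.1, 3.1, 28.0, None, 0.9),
]

#: (strain, substrate) keys of the rows whose printed titer is exactly
#: reproduced from the printed CDW and %CDW values; used by acceptance.
SELF_CONSISTENT_ROWS = (
    ("Cobetia sp. MC34", "acetate+valerate"),
    ("Cobetia sp. MC34", "glucose"),
    ("Cobetia sp. MC34", "fructose"),
    ("C. marina DSM 4741", "acetate"),
    ("C. marina DSM 4741", "acetate+valerate"),
    ("C. marina DSM 4741", "glucose"),
)


def cobetia_productivity_table() -> pd.DataFrame:
    """Printed productivity table as a DataFrame.

    Columns: strain, substrate, od_harvest, cdw_g_per_l, frac_3hb_pct,
    frac_3hv_pct (NaN where no valerate was fed), printed_pha_g_per_l.
    """
    return pd.DataFrame(
        _ROWS,
        columns=["strain", "substrate", "od_harvest", "cdw_g_per_l",
                 "frac_3hb_pct", "frac_3hv_pct", "printed_pha_g_per_l"],
    )
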