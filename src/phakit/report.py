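"""Report assembly: PhaC profile tables and productivity tables.

``run_profile`` turns a FASTA of PhaC candidates into one row per
record with MW, segmented pI values, box/AAKP annotation and the
variant call.  ``run_productivity`` turns a harvest table (CDW plus
monomer %CDW) into computed titers with per-group dispersion and flags
rows whose stated titer disagrees with the arithmetic.  Both are plain
functions over DataFrames; the CLI is a thin wrapper.
"""

from __future__ import annotations

import dataclasses
import json
from os import PathLike
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from phakit.growth import dispersion, pha_titer
from phakit.proteins import (
    DEFAULT_BOUNDARY,
    ProteinRecord,
    read_fasta,
    segment_profile,
)

__all__ = ["run_profile", "run_productivity", "profile_to_row",
           "write_profile_report", "PROFILE_COLUMNS"]

PROFILE_COLUMNS = ["record_id", "length_aa", "mw_kda", "pi_full", "pi_n613",
                   "pi_cterm", "cterm_len", "phac_box", "aakp_cterm",
                   "variant_call"]


def profile_to_row(profile) -> dict:
    """Flatten a SegmentedProfile into one report row.

    MW is reported to one decimal and pI values to two, matching the
    precision conventions of physicochemical summary tables.
    """
    boxes = ",".join(h.matched_seq for h in profile.phac_box_hits) or "-"
    return {
        "record_id": profile.record_id,
        "length_aa": profile.length_aa,
        "mw_kda": round(profile.mw_kda, 1),
        "pi_full": round(profile.pi_full, 2),
        "pi_n613": round(profile.pi_n_segment, 2),
        "pi_cterm": (round(profile.pi_c_segment, 2)
                     if profile.pi_c_segment is not None else np.nan),
        "cterm_len": profile.cterm_length_aa,
        "phac_box": boxes,
        "aakp_cterm": profile.aakp_count_cterm,
        "variant_call": profile.variant_call,
    }


def run_profile(records: list[ProteinRecord] | str | PathLike,
                boundary: int = DEFAULT_BOUNDARY,
                pka_set: str = "bjellqvist") -> tuple[pd.DataFrame, list[dict]]:
    """Profile every record; returns (table, motif-hit detail).

    ``records`` may be a FASTA path or a pre-parsed record list.  Rows
    follow input order.  The second return value holds the full MotifHit
    detail per record, suitable for JSON serialization.
    """
    if not isinstance(records, list):
        records = read_fasta(records)
    rows, details = [], []
    for rec in records:
        prof = segment_profile(rec, boundary=boundary, pka_set=pka_set)
        rows.append(profile_to_row(prof))
        details.append({
            "record_id": prof.record_id,
            "phac_box_hits": [dataclasses.asdict(h)
                              for h in prof.phac_box_hits],
            "aakp_count_cterm": prof.aakp_count_cterm,
        })
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS), details


def write_profile_report(table: pd.DataFrame, details: list[dict],
                         out_dir: str | PathLike,
                         stem: str = "phac_profile") -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv = out / f"{stem}.tsv"
    js = out / f"{stem}_motifs.json"
    table.to_csv(tsv, sep="\t", index=False)
    js.write_text(json.dumps(details, indent=2) + "\n")
    return tsv, js


def run_productivity(table: pd.DataFrame,
                     fraction_columns: Mapping[str, str] | None = None
                     ) -> pd.DataFrame:
    """Compute PHA titers for a harvest table and flag inconsistencies.

    ``table`` needs columns strain, substrate, cdw_g_per_l and one or
    more monomer fraction columns (default ``frac_3hb_pct`` and, when
    present, ``frac_3hv_pct``; NaN fractions count as absent monomers).
    A ``printed_pha_g_per_l`` column, when provided, is compared with
    the computed titer and disagreements flagged in ``consistent``.
    Rows with negative CDW or fractions are flagged in ``row_error``
    instead of aborting the run.  When a ``replicate`` column is
    present, per-(strain, substrate) dispersion of the computed titers
    (population SD, CV) is appended.
    """
    if fraction_columns is None:
        fraction_columns = {c: c.replace("frac_", "").replace("_pct", "")
                            for c in table.columns if c.startswith("frac_")}
    out = table.copy()
    computed, errors = [], []
    for _, row in table.iterrows():
        fracs = {name: float(row[col]) for col, name in fraction_columns.items()
                 if col in row and pd.notna(row[col])}
        try:
            computed.append(pha_titer(float(row["cdw_g_per_l"]), fracs))
            errors.append("")
        except (ValueError, KeyError) as exc:
            computed.append(np.nan)
            errors.append(str(exc))
    out["pha_g_per_l"] = computed
    out["row_error"] = errors
    if "printed_pha_g_per_l" in out.columns:
        printed = out["printed_pha_g_per_l"].astype(float)
        out["consistent"] = np.isclose(out["pha_g_per_l"], printed,
                                       atol=0.051) | printed.isna()
    if "replicate" in out.columns:
        stats = []
        for _, grp in out.groupby(["strain", "substrate"], sort=False):
            vals = grp["pha_g_per_l"].dropna()
            if len(vals):
                d = dispersion(vals)
                stats.extend([(d.mean, d.population_sd, d.cv)] * len(grp))
            else:
                stats.extend([(np.nan, np.nan, np.nan)] * len(grp))
        out[["group_mean", "group_sd", "group_cv"]] = pd.DataFrame(
            stats, index=out.index)
    return out
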