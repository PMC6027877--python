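"""Genetic-map resource outputs: per-kb tables, marker annotation, summaries.

These operations turn a fitted :class:`~hsmap.mapclean.MapModel` into the
community-facing resources: centimorgan values for every kilobase of the
physical assembly, cM annotation of arbitrary marker lists (SSLP-style), and
chromosome/genome summary tables with per-chromosome recombination rates.

Two genome-wide rate conventions exist: the unweighted mean of per-chromosome
rates (the headline convention — it reproduces the published 0.66 / 0.65
cM/Mb figures) and the weighted ratio of genome totals (total cM / total Mb).
Both are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _refdata
from .mapclean import MapModel
from .types import GeneticMap, HsmapError

__all__ = [
    "kb_grid",
    "annotate_markers",
    "summarize",
    "summarize_reference",
    "reference_chromosome_table",
]

TRACK_COLS = {"male": "cm_male", "female": "cm_female", "avg": "cm_avg"}


def kb_grid(model: MapModel, chromosome_lengths_bp, step_bp: int = 1000) -> pd.DataFrame:
    """Genetic positions at every ``step_bp`` of the physical map.

    Rows are emitted at bp = step, 2*step, ... up to the chromosome length,
    with all three cM tracks; columns are non-decreasing within each
    chromosome.
    """
    if step_bp < 1:
        raise HsmapError("step must be >= 1 bp")
    frames = []
    for chrom in model.chromosomes:
        if chrom not in chromosome_lengths_bp:
            raise HsmapError(f"no physical length for {chrom}")
        L = int(chromosome_lengths_bp[chrom])
        bp = np.arange(step_bp, L + 1, step_bp, dtype=np.int64)
        cols = {"chromosome": chrom, "position_bp": bp}
        for track, col in TRACK_COLS.items():
            cols[col] = np.maximum.accumulate(model.cm_at(chrom, bp, track=track))
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def annotate_markers(model: MapModel, markers: pd.DataFrame) -> pd.DataFrame:
    """Assign interpolated cM (all tracks) to a marker list.

    ``markers`` needs columns ``name``, ``chromosome``, ``position_bp``
    (the latter two may be null).  Markers with no position, a null
    chromosome, a chromosome absent from the model, or listed at multiple
    positions are flagged ``unmapped`` and given no cM.  Positions beyond
    the model's anchor range are extrapolated and flagged ``extrapolated``.
    """
    out = markers.copy().reset_index(drop=True)
    for col in TRACK_COLS.values():
        out[col] = np.nan
    out["flag"] = ""
    if len(out) == 0:
        return out
    multi = out["name"].map(out.groupby("name")["name"].count()) > 1
    no_pos = out["position_bp"].isna() | out["chromosome"].isna()
    known = out["chromosome"].isin(model.chromosomes) | out["chromosome"].isna()
    unmapped = (multi | no_pos | ~known).to_numpy()
    out.loc[unmapped, "flag"] = "unmapped"
    for chrom, sub in out.loc[~unmapped].groupby("chromosome", sort=False):
        bp = sub["position_bp"].to_numpy(float)
        flags = None
        for track, col in TRACK_COLS.items():
            cm, fl = model.cm_at(chrom, bp, track=track, return_flags=True)
            out.loc[sub.index, col] = cm
            flags = fl if flags is None else (flags | fl)
        idx = sub.index[flags]
        out.loc[idx, "flag"] = "extrapolated"
    return out


def _per_chrom_rows(chroms, n_markers, cm_m, cm_f, cm_a, mb):
    rows = []
    for i, chrom in enumerate(chroms):
        rate = round(cm_a[i] / mb[i], 2) if mb[i] > 0 else 0.0
        rows.append(
            {
                "chromosome": chrom,
                "n_markers": int(n_markers[i]),
                "cm_male": round(cm_m[i], 1),
                "cm_female": round(cm_f[i], 1),
                "cm_avg": round(cm_a[i], 1),
                "mb": round(mb[i], 1),
                "rate_cm_per_mb": rate,
                "cm_avg_raw": cm_a[i],
                "rate_raw": cm_a[i] / mb[i] if mb[i] > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def summarize(source, physical_lengths_bp=None, n_markers=None):
    """Chromosome-level and genome-level map summaries.

    ``source`` may be a :class:`GeneticMap` (totals from the last marker per
    chromosome, marker counts from the map) or a :class:`MapModel` (totals
    from terminal anchors; supply ``n_markers`` per chromosome if known).
    Physical sizes come from ``physical_lengths_bp`` (bp) when given,
    otherwise from the map's last marker position.

    Returns ``(per-chromosome DataFrame, genome summary dict)``.  The genome
    rate is reported under two conventions: ``rate_unweighted`` (mean of
    per-chromosome rates, the headline figure) and ``rate_weighted``
    (total cM / total Mb).  Report columns are rounded as on published
    summary tables (cM to 1 decimal, rates to 2); ``*_raw`` columns keep
    full precision.
    """
    if isinstance(source, GeneticMap):
        chroms = source.chromosomes
        cm_m = [source.chrom_total_cm(c, "male") for c in chroms]
        cm_f = [source.chrom_total_cm(c, "female") for c in chroms]
        cm_a = [source.chrom_total_cm(c, "avg") for c in chroms]
        counts = [len(source.chrom(c)) for c in chroms]
        last_bp = {c: float(source.chrom(c)["position_bp"].iloc[-1]) for c in chroms}
    elif isinstance(source, MapModel):
        chroms = source.chromosomes
        cm_m = [source.chrom_total_cm(c, "male") for c in chroms]
        cm_f = [source.chrom_total_cm(c, "female") for c in chroms]
        cm_a = [source.chrom_total_cm(c, "avg") for c in chroms]
        counts = [int((n_markers or {}).get(c, 0)) for c in chroms]
        last_bp = {c: float(source.anchors[(c, "avg")][0][-1]) for c in chroms}
    else:
        raise HsmapError("source must be a GeneticMap or MapModel")
    if physical_lengths_bp is None:
        physical_lengths_bp = last_bp
    mb = [float(physical_lengths_bp[c]) / 1e6 for c in chroms]
    table = _per_chrom_rows(chroms, counts, cm_m, cm_f, cm_a, mb)
    genome = {
        "n_markers": int(table["n_markers"].sum()),
        "cm_male": round(float(np.sum(cm_m)), 1),
        "cm_female": round(float(np.sum(cm_f)), 1),
        "cm_avg": round(float(np.sum(cm_a)), 1),
        "mb": round(float(np.sum(mb)), 1),
        "rate_unweighted": round(float(table["rate_cm_per_mb"].mean()), 2),
        "rate_weighted": round(float(np.sum(cm_a) / np.sum(mb)), 2) if np.sum(mb) > 0 else 0.0,
    }
    if genome["n_markers"] > 0:
        genome["resolution_cm"] = float(np.sum(cm_a)) / genome["n_markers"]
    return table, genome


def reference_chromosome_table() -> pd.DataFrame:
    """The bundled published chromosome summary (revised + historical maps)."""
    return _refdata.chromosome_table()


def summarize_reference(which: str = "revised"):
    """Genome summary arithmetic on the bundled published chromosome table.

    ``which`` selects the revised high-resolution map columns or the
    historical map columns.  Returns ``(per-chromosome DataFrame, genome
    summary dict)`` in the same shape as :func:`summarize`.
    """
    ref = _refdata.chromosome_table()
    if which == "revised":
        cm_m = ref["cm_male"].to_numpy(float)
        cm_f = ref["cm_female"].to_numpy(float)
        cm_a = ref["cm_avg"].to_numpy(float)
        mb = ref["mb"].to_numpy(float)
        counts = ref["n_markers"].to_numpy()
    elif which == "historical":
        cm_a = ref["hist_cm_avg"].to_numpy(float)
        cm_m = cm_f = cm_a  # sex-specific tracks were not available historically
        mb = ref["hist_mb"].to_numpy(float)
        counts = np.zeros(len(ref), dtype=int)
    else:
        raise HsmapError("which must be 'revised' or 'historical'")
    table = _per_chrom_rows(list(ref["chromosome"]), counts, cm_m, cm_f, cm_a, mb)
    tot = _refdata.GENOME_TOTALS
    # genome-level figures use the published totals row (whose physical-size
    # entry does not equal the chromosome-column sum; see docs/methods.md)
    if which == "revised":
        genome = {
            "n_markers": int(tot["n_markers"]),
            "cm_male": tot["cm_male"],
            "cm_female": tot["cm_female"],
            "cm_avg": tot["cm_avg"],
            "mb": tot["mb"],
            "rate_weighted": round(tot["cm_avg"] / tot["mb"], 2),
            "resolution_cm": tot["cm_avg"] / tot["n_markers"],
        }
    else:
        genome = {
            "n_markers": 0,
            "cm_avg": tot["hist_cm_avg"],
            "mb": tot["hist_mb"],
            "rate_weighted": round(tot["hist_cm_avg"] / tot["hist_mb"], 2),
        }
    genome["rate_unweighted"] = round(float(table["rate_cm_per_mb"].mean()), 2)
    return table, genome
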