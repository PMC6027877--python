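"""Genotype cleaning: monomorphic removal, Mendelian-error filtering, thinning.

The three stages mirror the cleaning applied to the HS rat cohort before map
construction: markers with fewer than two observed alleles are dropped,
markers whose cohort Mendelian-inheritance error rate exceeds 2% (strict) are
dropped, and the surviving panel is thinned to the first marker with
MAF > 0.05 (strict) per 10-kb window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeTable, HsmapError, MarkerPanel, Pedigree

__all__ = ["QcReport", "drop_monomorphic", "mendel_filter", "thin_by_window", "apply_qc"]


def _mendel_incompatibility_table() -> np.ndarray:
    """Boolean lookup ``T[sire, dam, offspring]`` for trio-incompatible dosages.

    A trio is incompatible when the offspring dosage cannot be formed by one
    allele from each parent.
    """
    tab = np.ones((3, 3, 3), dtype=bool)
    for s in range(3):
        for d in range(3):
            for a_s in ({0: (0,), 1: (0, 1), 2: (1,)}[s]):
                for a_d in ({0: (0,), 1: (0, 1), 2: (1,)}[d]):
                    tab[s, d, a_s + a_d] = False
    return tab


_MENDEL_INCOMPATIBLE = _mendel_incompatibility_table()


@dataclass
class QcReport:
    """Outcome of the QC stages on one genotype table."""

    mendel_rate: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    removed_monomorphic: list = field(default_factory=list)
    removed_mendel: list = field(default_factory=list)
    retained_after_thinning: list = field(default_factory=list)
    flagged_no_trios: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = self.mendel_rate.rename("mendel_rate").rename_axis("marker_id").reset_index()
        df["removed_mendel"] = df["marker_id"].isin(set(self.removed_mendel))
        df["no_complete_trio"] = df["marker_id"].isin(set(self.flagged_no_trios))
        return df


def drop_monomorphic(gt: GenotypeTable):
    """Remove markers showing fewer than two alleles among non-missing calls.

    All-missing markers count as monomorphic and are removed.
    """
    d = gt.dosage
    has_a = ((d == 0) | (d == 1)).any(axis=0)
    has_b = ((d == 2) | (d == 1)).any(axis=0)
    keep = has_a & has_b
    removed = list(gt.panel.marker_id[~keep])
    return gt.subset_markers(keep), removed


def mendel_rates(gt: GenotypeTable, ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker (error count, complete-trio count) over all pedigree trios.

    A single offspring call counts as one error regardless of how many
    Mendelian rules it violates.
    """
    trios = ped.trios()
    trios = trios[
        trios["individual_id"].map(gt.has)
        & trios["sire_id"].map(gt.has)
        & trios["dam_id"].map(gt.has)
    ]
    m = gt.panel.n_markers
    errors = np.zeros(m, dtype=np.int64)
    complete = np.zeros(m, dtype=np.int64)
    if len(trios) == 0:
        return errors, complete
    o = gt.dosage[gt.row_index(trios["individual_id"])]
    s = gt.dosage[gt.row_index(trios["sire_id"])]
    d = gt.dosage[gt.row_index(trios["dam_id"])]
    ok = (o >= 0) & (s >= 0) & (d >= 0)
    inc = np.zeros_like(ok)
    inc[ok] = _MENDEL_INCOMPATIBLE[s[ok], d[ok], o[ok]]
    errors += inc.sum(axis=0)
    complete += ok.sum(axis=0)
    return errors, complete


def mendel_filter(gt: GenotypeTable, ped: Pedigree, max_rate: float = 0.02):
    """Drop markers whose cohort Mendelian-error rate exceeds ``max_rate``.

    The rate is trio-incompatible offspring calls over complete trios; the
    inequality is strict (a marker exactly at the threshold is retained).
    Markers with no complete trio have an undefined rate and are retained but
    flagged.  Returns ``(filtered table, QcReport)``.
    """
    errors, complete = mendel_rates(gt, ped)
    with np.errstate(invalid="ignore"):
        rate = np.where(complete > 0, errors / np.maximum(complete, 1), np.nan)
    remove = (complete > 0) & (rate > max_rate)
    report = QcReport(
        mendel_rate=pd.Series(rate, index=pd.Index(gt.panel.marker_id, name="marker_id")),
        removed_mendel=list(gt.panel.marker_id[remove]),
        flagged_no_trios=list(gt.panel.marker_id[complete == 0]),
    )
    return gt.subset_markers(~remove), report


def thin_by_window(
    gt: GenotypeTable,
    panel: MarkerPanel | None = None,
    window_bp: int = 10_000,
    maf_min: float = 0.05,
) -> list:
    """Retain the first marker with MAF > ``maf_min`` per ``window_bp`` window.

    Windows are anchored at bp 1 on each chromosome and half-open on the
    right: window ``k`` covers ``[k*window_bp + 1, (k+1)*window_bp]``.  MAF is
    computed over all genotyped individuals.  Windows with no qualifying
    marker contribute nothing.  Returns the retained marker-id list in panel
    order.
    """
    panel = panel or gt.panel
    if panel.n_markers != gt.panel.n_markers or not np.array_equal(panel.marker_id, gt.panel.marker_id):
        raise HsmapError("panel does not match the genotype table")
    maf = gt.maf()
    qual = maf > maf_min
    retained = []
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        pos = panel.position_bp[sl]
        ids = panel.marker_id[sl]
        q = qual[sl]
        win = (pos - 1) // window_bp
        seen = set()
        for j in range(pos.size):
            if q[j] and win[j] not in seen:
                seen.add(win[j])
                retained.append(ids[j])
    return retained


def apply_qc(
    gt: GenotypeTable,
    ped: Pedigree,
    max_mendel_rate: float = 0.02,
    window_bp: int = 10_000,
    maf_min: float = 0.05,
):
    """Run the three QC stages in order; returns ``(clean table, QcReport)``."""
    gt1, mono = drop_monomorphic(gt)
    gt2, report = mendel_filter(gt1, ped, max_rate=max_mendel_rate)
    report.removed_monomorphic = mono
    retained = thin_by_window(gt2, window_bp=window_bp, maf_min=maf_min)
    report.retained_after_thinning = retained
    idx = gt2.panel.index_of(retained)
    return gt2.subset_markers(idx), report
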