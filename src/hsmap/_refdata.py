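"""Published reference tables for the laboratory rat genetic map.

Two chromosome-level summaries of the rat genetic map are bundled here:

* the revised high-resolution map estimated from 870 informative meioses in a
  heterogeneous-stock (HS) cohort, with sex-specific lengths, on the
  RGSC 6.0/rn6 physical assembly; and
* the historical (circa 2004, Jensen-Seaman) sex-averaged map on the
  Baylor 3.4/rn4 assembly.

These tables serve two purposes: they are the ground-truth recombination
landscape for the synthetic HS cohorts (``hsmap.simhs``), and they are the
inputs for the chromosome/genome summary arithmetic in ``hsmap.mapresources``.

Also bundled is the published old-map vs. new-map QTL comparison for an F2
(WKY x F344) cross: peak positions (cM) of immobility/climbing QTL under the
historical and revised sex-averaged maps, used by ``hsmap.qtlscan.compare_scans``
arithmetic checks.  ``None`` marks a QTL not detected under the revised map.
"""

from __future__ import annotations

import pandas as pd

# columns: chromosome, n_markers, male cM, female cM, sex-averaged cM,
# physical size (Mb, rn6) -- revised map; then sex-averaged cM and physical
# size (Mb, rn4) for the historical map.
_CHROM_ROWS = [
    # chrom, n_mark, male, female, avg,  mb_rn6, hist_avg, hist_mb
    ("chr1", 9098, 134.4, 146.0, 140.2, 282.8, 149.3, 267.4),
    ("chr2", 10440, 122.0, 135.5, 128.8, 266.4, 112.4, 255.3),
    ("chr3", 6142, 95.4, 113.1, 104.2, 177.7, 91.5, 166.0),
    ("chr4", 6930, 100.5, 110.7, 105.6, 184.2, 102.2, 186.1),
    ("chr5", 6859, 99.3, 111.8, 105.6, 173.7, 105.7, 171.6),
    ("chr6", 5747, 81.4, 94.9, 88.1, 148.0, 85.2, 134.2),
    ("chr7", 5157, 91.6, 99.4, 95.5, 145.7, 88.5, 141.6),
    ("chr8", 4759, 83.0, 99.6, 91.3, 133.3, 84.1, 126.8),
    ("chr9", 3761, 72.8, 83.9, 78.3, 122.1, 78.3, 109.5),
    ("chr10", 4479, 88.0, 94.3, 91.1, 112.6, 92.8, 101.2),
    ("chr11", 2788, 56.0, 66.8, 61.4, 90.5, 39.0, 73.6),
    ("chr12", 2108, 53.9, 52.4, 53.2, 52.7, 51.9, 43.6),
    ("chr13", 4869, 59.6, 70.3, 64.9, 114.0, 43.9, 75.1),
    ("chr14", 4519, 72.3, 74.1, 73.2, 115.5, 70.9, 105.7),
    ("chr15", 2991, 64.4, 79.2, 71.8, 111.2, 63.8, 106.1),
    ("chr16", 3806, 62.5, 61.0, 61.8, 90.7, 45.5, 76.6),
    ("chr17", 2679, 61.2, 74.4, 67.8, 90.8, 43.9, 91.0),
    ("chr18", 3223, 55.3, 63.1, 59.2, 88.2, 52.3, 84.7),
    ("chr19", 2360, 51.2, 58.5, 54.8, 62.3, 48.1, 56.4),
    ("chr20", 1890, 47.2, 54.7, 51.0, 56.2, 48.2, 50.6),
    ("chrX", 1165, 37.1, 82.8, 59.9, 160.0, 44.6, 130.8),
]

# genome totals as printed alongside the chromosome rows
GENOME_TOTALS = {
    "n_markers": 95769,
    "cm_male": 1589.0,
    "cm_female": 1826.0,
    "cm_avg": 1708.0,
    "mb": 2619.0,
    "rate": 0.66,
    "hist_cm_avg": 1542.0,
    "hist_mb": 2554.0,
    "hist_rate": 0.65,
}


def chromosome_table() -> pd.DataFrame:
    """Chromosome-level summary of the revised and historical rat maps."""
    return pd.DataFrame(
        _CHROM_ROWS,
        columns=[
            "chromosome", "n_markers", "cm_male", "cm_female", "cm_avg",
            "mb", "hist_cm_avg", "hist_mb",
        ],
    )


def rat_chromosome_lengths_bp() -> dict[str, int]:
    """Physical chromosome lengths (bp, RGSC 6.0/rn6) from the summary table."""
    return {r[0]: int(round(r[5] * 1e6)) for r in _CHROM_ROWS}


def rat_true_map_lengths_cm() -> dict[str, tuple[float, float]]:
    """Per-chromosome (male, female) genetic lengths in cM of the revised map."""
    return {r[0]: (r[2], r[3]) for r in _CHROM_ROWS}


# Old-map vs new-map QTL peak positions (cM) for the F2 depression-behaviour
# cross: (phenotype, model, chromosome, old peak, new peak).  A ``None`` new
# peak means the QTL was not detected with the revised map.
QTL_PEAK_ROWS = [
    ("immobility", "A", 3, 52.0, 66.0),
    ("immobility", "A", 5, 95.0, 102.0),
    ("immobility", "A", 8, 20.0, None),
    ("immobility", "B", 5, 95.0, 102.0),
    ("immobility", "B", 16, 26.0, 53.0),
    ("immobility", "C", 5, 95.0, 102.0),
    ("immobility", "C", 16, 6.0, 15.0),
    ("immobility", "D", 5, 95.0, 102.0),
    ("immobility", "D", 16, 6.0, 15.0),
    ("climbing", "A", 1, 99.0, 98.0),
    ("climbing", "A", 2, 58.0, 78.0),
    ("climbing", "A", 3, 34.0, 42.0),
    ("climbing", "A", 6, 1.0, 7.0),
    ("climbing", "A", 9, 76.0, 74.0),
    ("climbing", "B", 1, 99.0, 95.0),
    ("climbing", "B", 2, 58.0, 80.0),
    ("climbing", "B", 3, 34.0, 42.0),
    ("climbing", "B", 6, 1.0, 7.0),
    ("climbing", "B", 9, 76.0, 74.0),
    ("climbing", "B", 13, 10.0, 26.0),
    ("climbing", "B", 15, 2.0, 6.0),
    ("climbing", "B", 16, 24.0, 20.0),
    ("climbing", "B", 17, 42.0, 58.0),
    ("climbing", "C", 1, 99.0, 98.0),
    ("climbing", "C", 2, 58.0, 78.0),
    ("climbing", "C", 3, 34.0, 42.0),
    ("climbing", "C", 16, 22.0, 21.0),
    ("climbing", "D", 1, 99.0, 98.0),
    ("climbing", "D", 2, 58.0, 80.0),
    ("climbing", "D", 3, 34.0, 42.0),
    ("climbing", "D", 15, 2.0, 6.0),
    ("climbing", "D", 16, 22.0, 20.0),
    ("climbing", "D", 17, 42.0, 58.0),
]


def qtl_peak_table() -> pd.DataFrame:
    """Published QTL peaks under the historical and revised sex-averaged maps."""
    return pd.DataFrame(
        QTL_PEAK_ROWS,
        columns=["phenotype", "model", "chromosome", "old_peak_cm", "new_peak_cm"],
    )
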