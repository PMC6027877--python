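"""Readers/writers, run configuration and the end-to-end pipeline driver.

Tabular interchange is TSV with a header line (``#`` comments allowed);
genotypes travel as PED/MAP (PLINK dialect: PED columns family, individual,
sire, dam, sex 1/2, phenotype 0, then two allele columns per marker with
``0 0`` for missing; MAP columns chromosome, marker, cM, bp).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _refdata, genoqc, mapclean, mapestim, mapresources, simhs
from .types import (
    MISSING,
    MALE,
    FEMALE,
    GeneticMap,
    GenotypeTable,
    HsmapError,
    MarkerPanel,
    Pedigree,
    TrueRecombinationMap,
)

__all__ = [
    "read_pedmap",
    "write_pedmap",
    "read_genetic_map",
    "write_genetic_map",
    "read_tsv",
    "write_tsv",
    "RunConfig",
    "run_pipeline",
    "recover_map_lengths",
]

logger = logging.getLogger("hsmap")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[hsmap:%(stage)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


def write_tsv(df: pd.DataFrame, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# PED/MAP

_SEX_CODE = {MALE: "1", FEMALE: "2"}
_CODE_SEX = {"1": MALE, "2": FEMALE}


def write_pedmap(gt: GenotypeTable, ped: Pedigree, ped_path, map_path) -> None:
    panel = gt.panel
    mp = pd.DataFrame(
        {
            "chromosome": panel.chromosome,
            "marker_id": panel.marker_id,
            "cm": 0.0,
            "position_bp": panel.position_bp,
        }
    )
    mp.to_csv(map_path, sep="\t", index=False, header=False)
    a = panel.alleles
    rows_ped = ped.table.set_index("individual_id")
    with open(ped_path, "w") as fh:
        for ind in gt.individuals:
            r = rows_ped.loc[ind]
            d = gt.row(ind)
            cells = [
                str(r["family_id"]),
                str(ind),
                str(r["sire_id"]) if pd.notna(r["sire_id"]) else "0",
                str(r["dam_id"]) if pd.notna(r["dam_id"]) else "0",
                _SEX_CODE[r["sex"]],
                "0",
            ]
            al = np.empty((panel.n_markers, 2), dtype=object)
            al[:, :] = "0"
            known = d >= 0
            al[known & (d == 0)] = np.column_stack([a[known & (d == 0), 0]] * 2)
            al[known & (d == 2)] = np.column_stack([a[known & (d == 2), 1]] * 2)
            het = known & (d == 1)
            al[het] = a[het]
            fh.write(" ".join(cells) + " " + " ".join(al.ravel()) + "\n")


def _infer_generations(df: pd.DataFrame) -> pd.Series:
    gen = {}

    def depth(ind, seen=()):
        if ind in gen:
            return gen[ind]
        if ind in seen:
            raise HsmapError(f"pedigree cycle at {ind!r}")
        row = df.loc[df["individual_id"] == ind]
        s = row["sire_id"].iloc[0]
        if pd.isna(s):
            gen[ind] = 0
        else:
            gen[ind] = 1 + max(
                depth(s, seen + (ind,)), depth(row["dam_id"].iloc[0], seen + (ind,))
            )
        return gen[ind]

    for ind in df["individual_id"]:
        depth(ind)
    return df["individual_id"].map(gen)


def read_pedmap(ped_path, map_path):
    """Read a PED/MAP pair into ``(Pedigree, MarkerPanel, GenotypeTable)``.

    The round trip with :func:`write_pedmap` is lossless for genotypes and
    pedigree structure (generations are re-derived from parent links).
    """
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chromosome", "marker_id", "cm", "position_bp"]
    )
    n_mark = len(mp)
    fams, inds, sires, dams, sexes = [], [], [], [], []
    dosage_rows = []
    alleles_seen = [dict() for _ in range(n_mark)]
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_mark:
                raise HsmapError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_mark} fields, got {len(parts)}"
                )
            fam, ind, sire, dam, sex, _pheno = parts[:6]
            if sex not in _CODE_SEX:
                raise HsmapError(f"{ped_path} line {lineno}: sex code {sex!r} not in 1/2")
            fams.append(fam)
            inds.append(ind)
            sires.append(None if sire == "0" else sire)
            dams.append(None if dam == "0" else dam)
            sexes.append(_CODE_SEX[sex])
            al = np.array(parts[6:], dtype=object).reshape(n_mark, 2)
            dosage_rows.append((al, lineno))
    # allele dictionary per marker, in first-seen order
    for al, _ in dosage_rows:
        for j in range(n_mark):
            for sym in al[j]:
                if sym != "0" and sym not in alleles_seen[j]:
                    alleles_seen[j][sym] = len(alleles_seen[j])
    allele_pairs = np.empty((n_mark, 2), dtype=object)
    for j in range(n_mark):
        syms = list(alleles_seen[j]) + ["A", "B"]
        allele_pairs[j] = syms[:2]
        if len(alleles_seen[j]) > 2:
            raise HsmapError(f"marker {mp['marker_id'][j]}: more than two alleles in PED")
    dosage = np.full((len(dosage_rows), n_mark), MISSING, dtype=np.int8)
    for i, (al, lineno) in enumerate(dosage_rows):
        for j in range(n_mark):
            a1, a2 = al[j]
            if a1 == "0" or a2 == "0":
                continue
            try:
                dosage[i, j] = alleles_seen[j][a1] + alleles_seen[j][a2]
            except KeyError as exc:
                raise HsmapError(f"{ped_path} line {lineno}: allele {exc} outside panel") from exc
    panel = MarkerPanel(
        mp["marker_id"].to_numpy(object),
        mp["chromosome"].astype(str).to_numpy(object),
        mp["position_bp"].to_numpy(np.int64),
        allele_pairs,
    )
    df = pd.DataFrame(
        {
            "individual_id": inds,
            "sire_id": sires,
            "dam_id": dams,
            "sex": sexes,
            "family_id": fams,
        }
    )
    df["generation"] = _infer_generations(df)
    ped = Pedigree(df)
    return ped, panel, GenotypeTable(inds, panel, dosage)


# ---------------------------------------------------------------------------
# genetic-map tables

MAP_COLS = ["chromosome", "marker_id", "position_bp", "cm_male", "cm_female", "cm_avg"]


def write_genetic_map(gmap: GeneticMap, path) -> None:
    cols = MAP_COLS + (["offset_cm"] if gmap.frame["offset_cm"].abs().max() > 0 else [])
    write_tsv(gmap.frame[cols], path)


def read_genetic_map(path, validate_monotone: bool = True) -> GeneticMap:
    """Read a genetic-map TSV; monotonicity violations name their markers."""
    df = read_tsv(path)
    if df.empty:
        import warnings

        warnings.warn(f"{path}: empty genetic map")
        df = pd.DataFrame(columns=MAP_COLS)
    missing = [c for c in MAP_COLS if c not in df.columns]
    if missing:
        raise HsmapError(f"{path}: missing columns {missing}")
    return GeneticMap(df, validate_monotone=validate_monotone)


def write_truth(truth, path) -> None:
    rows = [
        {"individual_id": ind, "parent_role": role, "chromosome": chrom, "position_bp": int(bp)}
        for (ind, role, chrom), bps in truth.crossovers.items()
        for bp in bps
    ]
    write_tsv(pd.DataFrame(rows, columns=["individual_id", "parent_role", "chromosome", "position_bp"]), path)


# ---------------------------------------------------------------------------
# configuration and pipeline

@dataclass
class RunConfig:
    """Parameters of one pipeline run; unknown keys are rejected."""

    out_dir: str = "hsmap_out"
    seed: int = 1
    # simulation (used when no ped/map inputs are given)
    n_families: int = 65
    offspring_per_family: float = 870 / 2 / 65
    n_founder_strains: int = 8
    marker_spacing_bp: int = 100_000
    polymorphic_fraction: float = 0.85
    error_rate: float = 0.002
    missing_rate: float = 0.02
    mendel_bad_marker_fraction: float = 0.02
    displaced_fraction: float = 0.0
    displaced_min_shift_bp: int = 20_000_000
    chromosomes: dict = field(default_factory=dict)  # chrom -> [length_bp, male_cm, female_cm]
    # inputs (optional: run from existing PED/MAP instead of simulating)
    ped_path: str | None = None
    map_path: str | None = None
    cross_path: str | None = None
    # qc
    mendel_max_rate: float = 0.02
    window_bp: int = 10_000
    maf_min: float = 0.05
    # estimation
    mapping_function: str = "haldane"
    distortion_p_min: float = 0.001
    replicates: int = 0
    # cleaning
    loess_span: float = 0.1
    residual_threshold_cm: float = 1.0
    # resources
    kb_step_bp: int = 1000
    # qtl scan
    scan_step_cm: float = 2.0
    n_imputations: int = 64
    n_permutations: int = 1000
    alpha_significant: float = 0.05
    alpha_suggestive: float = 0.63

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise HsmapError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.seed is None:
            raise HsmapError("a seed is required for stochastic stages")
        for p in (self.ped_path, self.map_path, self.cross_path):
            if p is not None and not Path(p).exists():
                raise HsmapError(f"input path does not exist: {p}")
        if (self.ped_path is None) != (self.map_path is None):
            raise HsmapError("ped_path and map_path must be given together")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _default_chromosomes() -> dict:
    lengths = _refdata.rat_chromosome_lengths_bp()
    cms = _refdata.rat_true_map_lengths_cm()
    return {c: [lengths[c], cms[c][0], cms[c][1]] for c in lengths}


def recover_map_lengths(
    seed: int,
    n_seeds: int = 20,
    markers_per_chromosome: int = 2000,
    n_families: int = 65,
    offspring_per_family: float = 870 / 2 / 65,
    error_rate: float = 0.002,
    missing_rate: float = 0.02,
    displaced_fraction: float = 0.0,
    displaced_min_shift_bp: int = 20_000_000,
) -> pd.DataFrame:
    """Parameter-recovery study on the bundled rat genetic-map truth.

    For each replicate seed, simulates an HS cohort (65 families, ~870
    informative meioses, ~``markers_per_chromosome`` markers per chromosome)
    whose per-chromosome sex-specific genetic lengths are the published rat
    map, runs QC, estimation (Haldane) and cleaning, and records the
    recovered genome totals per track plus the truth.  Returns one row per
    seed with columns ``male, female, avg, true_male, true_female, true_avg``
    (and displaced/clean removal fractions when ``displaced_fraction > 0``).
    """
    lengths = _refdata.rat_chromosome_lengths_bp()
    cms = _refdata.rat_true_map_lengths_cm()
    true_map = TrueRecombinationMap.from_lengths(lengths, cms)
    spacing = {c: max(1000, L // markers_per_chromosome) for c, L in lengths.items()}
    true_m = sum(v[0] for v in cms.values())
    true_f = sum(v[1] for v in cms.values())
    rows = []
    for k in range(n_seeds):
        base = (int(seed) * 10_000 + k * 97) % (2**31 - 1)
        panel = simhs.make_marker_panel(lengths, spacing, seed=base)
        ped = simhs.build_hs_pedigree(n_families, offspring_per_family, 8, seed=base + 1)
        founders = simhs.simulate_founder_haplotypes(panel, 8, seed=base + 2)
        gt, truth = simhs.simulate_cohort(
            ped, founders, true_map, error_rate=error_rate, missing_rate=missing_rate, seed=base + 3
        )
        displaced: list = []
        if displaced_fraction > 0:
            panel2, displaced = simhs.corrupt_marker_positions(
                panel, displaced_fraction, displaced_min_shift_bp, seed=base + 4,
                chromosome_lengths_bp=lengths,
            )
            gt = gt.reorder_to(panel2)
        gt, _ = genoqc.apply_qc(gt, ped)
        gmap, _ = mapestim.estimate_map(gt, ped, mapping_function="haldane")
        cleaned, report = mapclean.clean_map(gmap)
        row = {
            "seed": base,
            "male": cleaned.total_cm("male"),
            "female": cleaned.total_cm("female"),
            "avg": cleaned.total_cm("avg"),
            "true_male": true_m,
            "true_female": true_f,
            "true_avg": (true_m + true_f) / 2,
            "n_meioses": ped.n_informative_meioses(),
        }
        if displaced:
            removed = set(report.removed)
            disp = set(displaced) & set(gt.panel.marker_id)
            clean_ids = set(gt.panel.marker_id) - set(displaced)
            row["displaced_removed_frac"] = len(removed & disp) / len(disp)
            row["clean_removed_frac"] = len(removed & clean_ids) / len(clean_ids)
        rows.append(row)
        _log("recovery", f"seed {k + 1}/{n_seeds}: avg {row['avg']:.1f} cM")
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate → qc → estimate → clean → resources (→ scan).

    Every stage writes its artifacts under ``config.out_dir`` and appends to
    a manifest recording stage, parameters, seed and input digests.  Raises
    with the failing stage's name on error.  Returns a dict of headline
    results (map totals, summaries, file paths).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    results: dict = {}

    def record(stage, params, files):
        manifest.append(
            {
                "stage": stage,
                "seed": config.seed,
                "parameters": params,
                "artifacts": {f.name: _digest(f) for f in files},
            }
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    def stage(name):
        def deco(fn):
            def wrapper(*a, **kw):
                _log(name, "running")
                try:
                    return fn(*a, **kw)
                except Exception as exc:
                    raise HsmapError(f"stage {name!r} failed: {exc}") from exc

            return wrapper

        return deco

    @stage("simulate")
    def do_simulate():
        chrom_cfg = config.chromosomes or _default_chromosomes()
        lengths = {c: int(v[0]) for c, v in chrom_cfg.items()}
        cms = {c: (float(v[1]), float(v[2])) for c, v in chrom_cfg.items()}
        true_map = TrueRecombinationMap.from_lengths(lengths, cms)
        panel = simhs.make_marker_panel(lengths, config.marker_spacing_bp, seed=config.seed)
        ped = simhs.build_hs_pedigree(
            config.n_families, config.offspring_per_family, config.n_founder_strains, seed=config.seed + 1
        )
        founders = simhs.simulate_founder_haplotypes(
            panel, config.n_founder_strains, config.polymorphic_fraction, seed=config.seed + 2
        )
        gt, truth = simhs.simulate_cohort(
            ped,
            founders,
            true_map,
            error_rate=config.error_rate,
            missing_rate=config.missing_rate,
            mendel_bad_marker_fraction=config.mendel_bad_marker_fraction,
            seed=config.seed + 3,
        )
        if config.displaced_fraction > 0:
            panel2, displaced = simhs.corrupt_marker_positions(
                panel, config.displaced_fraction, config.displaced_min_shift_bp,
                seed=config.seed + 4, chromosome_lengths_bp=lengths,
            )
            gt = gt.reorder_to(panel2)
            truth.displaced_markers = displaced
        write_pedmap(gt, ped, out / "cohort.ped", out / "cohort.map")
        write_truth(truth, out / "truth_crossovers.tsv")
        write_tsv(true_map.to_frame(), out / "true_map.tsv")
        record(
            "simulate",
            {k: getattr(config, k) for k in (
                "n_families", "offspring_per_family", "n_founder_strains", "marker_spacing_bp",
                "error_rate", "missing_rate", "mendel_bad_marker_fraction", "displaced_fraction")},
            [out / "cohort.ped", out / "cohort.map", out / "truth_crossovers.tsv", out / "true_map.tsv"],
        )
        return gt, ped, true_map, truth

    if config.ped_path:
        _log("input", f"reading {config.ped_path}")
        ped, _, gt = read_pedmap(config.ped_path, config.map_path)
        true_map = None
        truth = None
    else:
        gt, ped, true_map, truth = do_simulate()

    @stage("qc")
    def do_qc(gt):
        clean, report = genoqc.apply_qc(
            gt, ped, max_mendel_rate=config.mendel_max_rate,
            window_bp=config.window_bp, maf_min=config.maf_min,
        )
        write_tsv(report.to_frame(), out / "qc_report.tsv")
        record("qc", {"mendel_max_rate": config.mendel_max_rate, "window_bp": config.window_bp,
                      "maf_min": config.maf_min}, [out / "qc_report.tsv"])
        results["n_markers_after_qc"] = clean.panel.n_markers
        return clean

    gt = do_qc(gt)

    @stage("estimate")
    def do_estimate(gt):
        gmap, diag = mapestim.estimate_map(
            gt, ped, mapping_function=config.mapping_function,
            distortion_p_min=config.distortion_p_min,
            replicates=config.replicates, seed=config.seed + 5,
        )
        write_genetic_map(gmap, out / "genetic_map_raw.tsv")
        record("estimate", {"mapping_function": config.mapping_function,
                            "distortion_p_min": config.distortion_p_min,
                            "replicates": config.replicates},
               [out / "genetic_map_raw.tsv"])
        results["n_meioses"] = diag["n_meioses"]
        return gmap

    gmap = do_estimate(gt)

    @stage("clean")
    def do_clean(gmap):
        cleaned, report = mapclean.clean_map(
            gmap, span=config.loess_span, threshold_cm=config.residual_threshold_cm
        )
        write_genetic_map(cleaned, out / "genetic_map_clean.tsv")
        write_tsv(report.frame, out / "cleaning_report.tsv")
        record("clean", {"span": config.loess_span, "threshold_cm": config.residual_threshold_cm},
               [out / "genetic_map_clean.tsv", out / "cleaning_report.tsv"])
        results["n_markers_removed_by_cleaning"] = len(report.removed)
        return cleaned

    cleaned = do_clean(gmap)

    @stage("resources")
    def do_resources(cleaned):
        model = mapclean.fit_map_model(cleaned)
        model_path = out / "map_model_anchors.tsv"
        write_tsv(model.to_frame(), model_path)
        chrom_cfg = config.chromosomes or _default_chromosomes()
        lengths = {c: int(v[0]) for c, v in chrom_cfg.items() if c in model.chromosomes}
        grid = mapresources.kb_grid(model, lengths, step_bp=config.kb_step_bp)
        write_tsv(grid, out / "per_kb_map.tsv")
        table, genome = mapresources.summarize(cleaned, {c: lengths[c] for c in lengths})
        write_tsv(table, out / "chromosome_summary.tsv")
        record("resources", {"kb_step_bp": config.kb_step_bp},
               [model_path, out / "per_kb_map.tsv", out / "chromosome_summary.tsv"])
        results["genome_summary"] = genome
        results["cm_total_male"] = cleaned.total_cm("male")
        results["cm_total_female"] = cleaned.total_cm("female")
        results["cm_total_avg"] = cleaned.total_cm("avg")
        return model

    do_resources(cleaned)

    if config.cross_path:
        @stage("scan")
        def do_scan():
            from . import qtlscan

            cross = qtlscan.read_cross(config.cross_path)
            pheno = cross.phenotypes.columns[0]
            imps = qtlscan.impute_genotypes(
                cross, step_cm=config.scan_step_cm,
                n_imputations=config.n_imputations, seed=config.seed + 6,
            )
            scan = qtlscan.lod_scan(imps, pheno)
            scan.thresholds = qtlscan.permutation_thresholds(
                imps, pheno, n_perm=config.n_permutations,
                alphas=(config.alpha_significant, config.alpha_suggestive),
                seed=config.seed + 7,
            )
            write_tsv(scan.frame, out / "qtl_scan.tsv")
            peaks = qtlscan.find_peaks(scan, scan.thresholds[config.alpha_suggestive])
            write_tsv(peaks, out / "qtl_peaks.tsv")
            record("scan", {"step_cm": config.scan_step_cm, "n_imputations": config.n_imputations,
                            "n_permutations": config.n_permutations},
                   [out / "qtl_scan.tsv", out / "qtl_peaks.tsv"])
            results["qtl_thresholds"] = scan.thresholds

        do_scan()

    if truth is not None and truth.displaced_markers:
        results["displaced_markers"] = truth.displaced_markers
    results["out_dir"] = str(out)
    _log("done", f"{len(manifest)} stages complete")
    return results
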