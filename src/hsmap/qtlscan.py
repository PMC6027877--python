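"""Single-locus F2 interval mapping by multiple imputation.

Unobserved genotypes on a cM grid (default 2 cM step) are repeatedly sampled
from their joint distribution given the typed flanking markers under a
Markov model along the genetic map (Haldane recombination probabilities,
error-free genotypes).  At each grid position the LOD compares the QTL model
(covariates + additive + dominance terms) against the covariate-only null,
and imputations are combined as ``log10`` of the mean of ``10^LOD``.
Genome-wide significance comes from permutation of the phenotype; peak
localisation uses Bayes credible intervals over the normalised ``10^LOD``
profile.  Old-map vs new-map scans are compared by peak shifts (> 10 cM
flags a re-localised QTL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import HsmapError

__all__ = [
    "F2Cross",
    "ImputationSet",
    "QtlScan",
    "read_cross",
    "write_cross",
    "simulate_f2_cross",
    "impute_genotypes",
    "lod_scan",
    "permutation_thresholds",
    "bayes_interval",
    "find_peaks",
    "compare_peaks",
    "compare_scans",
]

GENO_CODES = {"AA": 0, "AB": 1, "BB": 2, "-": -1}
CODE_GENO = {v: k for k, v in GENO_CODES.items()}


@dataclass
class F2Cross:
    """An F2 intercross: phenotypes/covariates, genotypes and a marker map.

    ``genotypes`` codes AA/AB/BB as 0/1/2 (B = second founder allele),
    missing as -1.  ``marker_map`` has columns ``name, chromosome, cm`` and
    is sorted by cM within chromosome.
    """

    phenotypes: pd.DataFrame
    genotypes: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.phenotypes), len(self.marker_map)):
            raise HsmapError("genotype matrix does not match phenotypes x markers")
        for _, sub in self.marker_map.groupby("chromosome", sort=False):
            if np.any(np.diff(sub["cm"].to_numpy(float)) < 0):
                raise HsmapError("markers must be sorted by cM within chromosome")

    @property
    def chromosomes(self) -> list:
        seen, out = set(), []
        for c in self.marker_map["chromosome"]:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def with_map(self, new_cm) -> "F2Cross":
        """Same genotypes under repositioned marker cM (dict name -> cm)."""
        mm = self.marker_map.copy()
        mm["cm"] = [new_cm[n] for n in mm["name"]]
        order = np.lexsort((mm["cm"].to_numpy(float), mm.groupby("chromosome", sort=False).ngroup()))
        return F2Cross(self.phenotypes.copy(), self.genotypes[:, order], mm.iloc[order].reset_index(drop=True))


def read_cross(path) -> F2Cross:
    """Read a comma-separated cross file (R/qtl "csv" dialect).

    Row 1: phenotype/covariate names then marker names; row 2: empty cells
    for phenotypes, chromosome per marker; row 3: empty cells, cM per
    marker; then one row per individual with phenotype values and genotype
    codes AA/AB/BB/- .
    """
    raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    names = list(raw.iloc[0])
    chrom_row = list(raw.iloc[1])
    cm_row = list(raw.iloc[2])
    n_pheno = sum(1 for c in chrom_row if c == "")
    pheno_names = names[:n_pheno]
    marker_names = names[n_pheno:]
    mm = pd.DataFrame(
        {
            "name": marker_names,
            "chromosome": chrom_row[n_pheno:],
            "cm": [float(x) for x in cm_row[n_pheno:]],
        }
    )
    body = raw.iloc[3:]
    phen = body.iloc[:, :n_pheno].replace("", np.nan).astype(float)
    phen.columns = pheno_names
    phen = phen.reset_index(drop=True)
    geno = body.iloc[:, n_pheno:].to_numpy(str)
    try:
        g = np.vectorize(lambda s: GENO_CODES[s if s else "-"])(geno).astype(np.int8)
    except KeyError as exc:  # pragma: no cover - malformed input
        raise HsmapError(f"unknown genotype code {exc}") from exc
    return F2Cross(phen, g, mm)


def write_cross(cross: F2Cross, path) -> None:
    pheno_cols = list(cross.phenotypes.columns)
    header = pheno_cols + list(cross.marker_map["name"])
    row2 = [""] * len(pheno_cols) + [str(c) for c in cross.marker_map["chromosome"]]
    row3 = [""] * len(pheno_cols) + [f"{x:g}" for x in cross.marker_map["cm"]]
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        fh.write(",".join(row2) + "\n")
        fh.write(",".join(row3) + "\n")
        for i in range(len(cross.phenotypes)):
            ph = [
                "" if pd.isna(v) else f"{v:g}" for v in cross.phenotypes.iloc[i]
            ]
            gn = [CODE_GENO[int(v)] for v in cross.genotypes[i]]
            fh.write(",".join(ph + gn) + "\n")


# ---------------------------------------------------------------------------
# genotype model along the map

def _transition(r: float) -> np.ndarray:
    """F2 genotype transition matrix across an interval with rec. fraction r."""
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


_F2_PRIOR = np.array([0.25, 0.5, 0.25])


def _haldane_r(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cm, float) / 50.0))


def simulate_f2_cross(
    n_individuals: int,
    chromosome_lengths_cm,
    marker_step_cm: float = 10.0,
    qtl=None,
    residual_sd: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    phenotype_name: str = "pheno",
):
    """Simulate an F2 cross with an optional planted QTL.

    ``qtl`` is ``(chromosome, cm, additive, dominance)``; the phenotype is
    ``additive*(g-1) + dominance*1[g=het] + N(0, residual_sd)``.  Markers sit
    every ``marker_step_cm``.  Returns ``(F2Cross, truth dict)``.
    """
    rng = np.random.default_rng(seed)
    names, chroms, cms, genos = [], [], [], []
    qtl_geno = None
    for chrom, L in chromosome_lengths_cm.items():
        pos = list(np.arange(0.0, float(L) + 1e-9, marker_step_cm))
        sim_pos = sorted(set(pos) | ({float(qtl[1])} if qtl and qtl[0] == chrom else set()))
        sim_pos = np.asarray(sim_pos)
        z = np.empty((n_individuals, sim_pos.size), dtype=np.int8)
        z[:, 0] = rng.choice(3, size=n_individuals, p=_F2_PRIOR)
        for j in range(1, sim_pos.size):
            T = _transition(float(_haldane_r(sim_pos[j] - sim_pos[j - 1])))
            u = rng.random(n_individuals)
            cum = np.cumsum(T[z[:, j - 1]], axis=1)
            z[:, j] = (u[:, None] > cum).sum(axis=1)
        if qtl and qtl[0] == chrom:
            qi = int(np.argmin(np.abs(sim_pos - float(qtl[1]))))
            qtl_geno = z[:, qi].copy()
        keep = np.isin(sim_pos, pos)
        z = z[:, keep]
        sim_pos = sim_pos[keep]
        for j, p in enumerate(sim_pos):
            names.append(f"{chrom}m{j:03d}")
            chroms.append(chrom)
            cms.append(float(p))
        genos.append(z)
    G = np.concatenate(genos, axis=1)
    if missing_rate > 0:
        G[rng.random(G.shape) < missing_rate] = -1
    y = rng.normal(0.0, residual_sd, size=n_individuals)
    if qtl is not None:
        a, dom = float(qtl[2]), float(qtl[3])
        y = y + a * (qtl_geno - 1.0) + dom * (qtl_geno == 1)
    phen = pd.DataFrame({phenotype_name: y})
    cross = F2Cross(phen, G, pd.DataFrame({"name": names, "chromosome": chroms, "cm": cms}))
    truth = {"qtl": qtl, "qtl_genotype": qtl_geno}
    return cross, truth


@dataclass
class ImputationSet:
    """Sampled full-genome genotypes on the scan grid for each imputation."""

    cross: F2Cross
    step_cm: float
    positions: dict  # chrom -> cm array (markers + pseudomarkers)
    is_marker: dict  # chrom -> bool array
    draws: dict  # chrom -> uint8 array (n_individuals, n_imputations, n_positions)
    n_imputations: int


def impute_genotypes(
    cross: F2Cross,
    step_cm: float = 2.0,
    n_imputations: int = 128,
    seed: int = 0,
) -> ImputationSet:
    """Sample grid genotypes given typed markers (forward-filter backward-sample).

    The grid per chromosome is the union of marker positions and a regular
    ``step_cm`` lattice from the first to the last marker.  Observed marker
    genotypes are reproduced exactly in every imputation; draws are
    deterministic under a fixed seed.
    """
    if step_cm <= 0 or n_imputations < 1:
        raise HsmapError("step must be positive and n_imputations >= 1")
    rng = np.random.default_rng(seed)
    n = len(cross.phenotypes)
    positions, is_marker, draws = {}, {}, {}
    for chrom in cross.chromosomes:
        sel = (cross.marker_map["chromosome"] == chrom).to_numpy()
        mpos = cross.marker_map.loc[sel, "cm"].to_numpy(float)
        if mpos.size == 0:
            import warnings

            warnings.warn(f"chromosome {chrom}: no markers, skipped")
            continue
        lattice = np.arange(mpos[0], mpos[-1] + 1e-9, step_cm)
        grid = np.unique(np.round(np.concatenate([mpos, lattice, mpos[-1:]]), 9))
        G = grid.size
        obs = np.full((n, G), -1, dtype=np.int8)
        midx = np.searchsorted(grid, np.round(mpos, 9))
        obs[:, midx] = cross.genotypes[:, sel]
        # forward filtering
        alphas = np.empty((G, n, 3))
        emis = np.ones((n, 3))
        a = np.broadcast_to(_F2_PRIOR, (n, 3)).copy()
        trans = [None] * G
        for g in range(G):
            if g > 0:
                T = _transition(float(_haldane_r(grid[g] - grid[g - 1])))
                trans[g] = T
                a = a @ T
            o = obs[:, g]
            emis[:] = 1.0
            typed = o >= 0
            emis[typed] = 0.0
            emis[typed, o[typed]] = 1.0
            a = a * emis
            tot = a.sum(axis=1, keepdims=True)
            tot[tot == 0] = 1.0  # impossible configuration: fall back to prior
            a = a / tot
            alphas[g] = a
        # backward sampling, vectorised over individuals and imputations
        z = np.empty((n, n_imputations, G), dtype=np.uint8)
        z[:, :, G - 1] = _sample_categorical(np.repeat(alphas[G - 1][:, None, :], n_imputations, axis=1), rng)
        for g in range(G - 2, -1, -1):
            T = trans[g + 1]
            znext = z[:, :, g + 1]
            probs = alphas[g][:, None, :] * np.moveaxis(T[:, znext], 0, -1)
            z[:, :, g] = _sample_categorical(probs, rng)
        draws[chrom] = z
        positions[chrom] = grid
        is_marker[chrom] = np.isin(np.arange(G), midx)
    return ImputationSet(cross, step_cm, positions, is_marker, draws, n_imputations)


def _sample_categorical(probs: np.ndarray, rng) -> np.ndarray:
    """Draw indices from unnormalised probabilities along the last axis."""
    cum = np.cumsum(probs, axis=-1)
    tot = cum[..., -1:]
    tot = np.where(tot == 0, 1.0, tot)
    u = rng.random(probs.shape[:-1])[..., None] * tot
    return (u > cum).sum(axis=-1).astype(np.uint8)


# ---------------------------------------------------------------------------
# LOD scan

@dataclass
class QtlScan:
    """LOD curve on a fixed-step genome grid with thresholds and peaks."""

    frame: pd.DataFrame  # chromosome, cm, lod, is_marker, flagged
    step_cm: float
    phenotype: str
    model: str = "A"
    thresholds: dict = field(default_factory=dict)

    def chrom(self, chrom) -> pd.DataFrame:
        return self.frame.loc[self.frame["chromosome"] == chrom]

    def max_lod(self) -> float:
        return float(np.nanmax(self.frame["lod"].to_numpy(float)))


def _design_rows(phenotypes: pd.DataFrame, phenotype: str, covariates):
    y = phenotypes[phenotype].to_numpy(float)
    covs = [phenotypes[c].to_numpy(float) for c in (covariates or [])]
    ok = np.isfinite(y)
    for c in covs:
        ok &= np.isfinite(c)
    X0 = np.column_stack([np.ones(ok.sum())] + [c[ok] for c in covs])
    return y[ok], X0, ok


def _rss(X: np.ndarray, Y: np.ndarray):
    """Residual sums of squares of columns of Y on X, plus the design rank."""
    Q, R = np.linalg.qr(X)
    rank = int((np.abs(np.diag(R)) > 1e-9 * max(1.0, np.abs(R[0, 0]))).sum())
    proj = Q.T @ Y
    return np.maximum((Y**2).sum(axis=0) - (proj**2).sum(axis=0), 1e-300), rank


def _combine_lods(lods: np.ndarray, axis: int = 0) -> np.ndarray:
    """Imputation-averaged LOD: log10 of the mean of 10^LOD."""
    m = np.max(lods, axis=axis, keepdims=True)
    out = m + np.log10(np.mean(10.0 ** (lods - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


def lod_scan(
    imputations: ImputationSet,
    phenotype: str,
    covariates=None,
    interacting_covariates=None,
    model: str = "A",
) -> QtlScan:
    """Genome scan: imputation-averaged LOD at every grid position.

    At each position, LOD = (n/2) log10(RSS0/RSS1) comparing covariates-only
    to covariates + additive + dominance genotype terms (plus
    covariate-by-genotype interactions when ``interacting_covariates`` are
    named), averaged over imputations on the 10^LOD scale.  Positions with a
    rank-deficient QTL design are flagged.
    """
    cross = imputations.cross
    y, X0, rows = _design_rows(cross.phenotypes, phenotype, covariates)
    if y.size < 10:
        raise HsmapError("need at least 10 phenotyped individuals")
    n = y.size
    rss0, _ = _rss(X0, y[:, None])
    inter = [cross.phenotypes[c].to_numpy(float)[rows] for c in (interacting_covariates or [])]
    recs = []
    for chrom, grid in imputations.positions.items():
        Z = imputations.draws[chrom][rows]
        G = grid.size
        lods = np.empty((imputations.n_imputations, G))
        flagged = np.zeros(G, bool)
        full_rank = X0.shape[1] + 2 + 2 * len(inter)
        for g in range(G):
            for m in range(imputations.n_imputations):
                zg = Z[:, m, g].astype(float)
                add = zg - 1.0
                dom = (zg == 1.0).astype(float)
                cols = [X0, add[:, None], dom[:, None]]
                for c in inter:
                    cols.append((c * add)[:, None])
                    cols.append((c * dom)[:, None])
                X = np.column_stack(cols)
                rss1, rank = _rss(X, y[:, None])
                if rank < full_rank:
                    flagged[g] = True
                lods[m, g] = 0.5 * n * np.log10(rss0[0] / rss1[0])
        comb = _combine_lods(lods, axis=0)
        recs.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "cm": grid,
                    "lod": np.maximum(comb, 0.0),
                    "is_marker": imputations.is_marker[chrom],
                    "flagged": flagged,
                }
            )
        )
    return QtlScan(pd.concat(recs, ignore_index=True), imputations.step_cm, phenotype, model=model)


def permutation_thresholds(
    imputations: ImputationSet,
    phenotype: str,
    covariates=None,
    n_perm: int = 1000,
    alphas=(0.05, 0.63),
    seed: int = 0,
) -> dict:
    """Genome-wide LOD thresholds from phenotype permutations.

    The phenotype is permuted against the (fixed) imputed genotypes; the
    threshold at level ``alpha`` is the ``1 - alpha`` quantile of the
    per-permutation genome-wide maximum LOD.
    """
    if n_perm < 100:
        raise HsmapError("use at least 100 permutations")
    cross = imputations.cross
    y, X0, rows = _design_rows(cross.phenotypes, phenotype, covariates)
    if np.ptp(y) == 0:
        raise HsmapError("constant phenotype")
    n = y.size
    rng = np.random.default_rng(seed)
    Y = np.empty((n, n_perm))
    for p in range(n_perm):
        Y[:, p] = y[rng.permutation(n)]
    rss0, _ = _rss(X0, Y)
    gmax = np.full(n_perm, -np.inf)
    for chrom, grid in imputations.positions.items():
        Z = imputations.draws[chrom][rows]
        for g in range(grid.size):
            lods = np.empty((imputations.n_imputations, n_perm))
            for m in range(imputations.n_imputations):
                zg = Z[:, m, g].astype(float)
                X = np.column_stack([X0, zg[:, None] - 1.0, (zg == 1.0).astype(float)[:, None]])
                rss1, _ = _rss(X, Y)
                lods[m] = 0.5 * n * np.log10(rss0 / rss1)
            gmax = np.maximum(gmax, _combine_lods(lods, axis=0))
    return {float(a): float(np.quantile(gmax, 1.0 - a)) for a in alphas}


def bayes_interval(scan: QtlScan, chromosome, coverage: float = 0.95):
    """Smallest consecutive grid window around the peak holding ``coverage`` mass.

    Posterior mass is proportional to 10^LOD over the chromosome's grid
    points; the window must contain the peak (ties at the peak broken to
    lowest cM); among minimal-width windows the leftmost is returned, as
    ``(cm_low, cm_high)``.
    """
    sub = scan.chrom(chromosome)
    if len(sub) == 0:
        raise HsmapError(f"no grid points on chromosome {chromosome}")
    cm = sub["cm"].to_numpy(float)
    lod = np.nan_to_num(sub["lod"].to_numpy(float), nan=-np.inf)
    w = 10.0 ** (lod - np.max(lod))
    w = w / w.sum()
    peak = int(np.argmax(lod))
    best = None
    for i in range(peak, -1, -1):
        for j in range(peak, cm.size):
            width = j - i
            if best is not None and width >= best[0]:
                continue
            if w[i : j + 1].sum() >= coverage - 1e-12:
                if best is None or width < best[0] or (width == best[0] and i < best[1]):
                    best = (width, i, j)
    if best is None:
        best = (cm.size - 1, 0, cm.size - 1)
    _, i, j = best
    return float(cm[i]), float(cm[j])


def find_peaks(scan: QtlScan, suggestive: float, coverage: float = 0.95) -> pd.DataFrame:
    """Per-chromosome peak table; detected = peak LOD exceeds ``suggestive``."""
    rows = []
    for chrom in dict.fromkeys(scan.frame["chromosome"]):
        sub = scan.chrom(chrom)
        lod = np.nan_to_num(sub["lod"].to_numpy(float), nan=-np.inf)
        i = int(np.argmax(lod))  # argmax takes the first (lowest cM) maximum
        detected = bool(lod[i] > suggestive)
        lo, hi = bayes_interval(scan, chrom, coverage) if detected else (np.nan, np.nan)
        rows.append(
            {
                "phenotype": scan.phenotype,
                "model": scan.model,
                "chromosome": chrom,
                "peak_cm": float(sub["cm"].to_numpy(float)[i]) if detected else np.nan,
                "peak_lod": float(lod[i]),
                "ci_lo": lo,
                "ci_hi": hi,
                "detected": detected,
            }
        )
    return pd.DataFrame(rows)


def compare_peaks(old: pd.DataFrame, new: pd.DataFrame, shift_threshold_cm: float = 10.0):
    """Old-map vs new-map QTL comparison from peak tables.

    Input frames need columns ``phenotype, model, chromosome, peak_cm``
    (NaN/absent = not detected).  QTL are matched on the three keys
    (duplicates are an error).  The shift ``|new - old|`` is defined only
    where a QTL is detected in both scans, and flagged when strictly greater
    than ``shift_threshold_cm``.  The summary's ``n_qtl`` counts QTL
    comparable under both maps, as published comparisons do; rows undetected
    in one map are reported but excluded from that denominator.
    """
    keys = ["phenotype", "model", "chromosome"]
    for df in (old, new):
        if df.duplicated(subset=keys).any():
            raise HsmapError("duplicate QTL rows for a (phenotype, model, chromosome) key")
    merged = old.merge(new, on=keys, how="outer", suffixes=("_old", "_new"))
    both = merged["peak_cm_old"].notna() & merged["peak_cm_new"].notna()
    merged["detected_in_both"] = both
    merged["shift_cm"] = np.where(both, (merged["peak_cm_new"] - merged["peak_cm_old"]).abs(), np.nan)
    merged["shifted"] = both & (merged["shift_cm"] > shift_threshold_cm)
    summary = {
        "n_rows": int(len(merged)),
        "n_qtl": int(both.sum()),
        "n_shifted": int(merged["shifted"].sum()),
        "n_undetected": int((~both).sum()),
    }
    return merged, summary


def compare_scans(
    old_scans,
    new_scans,
    suggestive_old: float,
    suggestive_new: float,
    shift_threshold_cm: float = 10.0,
    coverage: float = 0.95,
):
    """Compare matched QTL scans run under the old and new genetic maps.

    ``old_scans``/``new_scans`` are matched lists of :class:`QtlScan` (same
    phenotype/model pairs).  QTL are chromosomes whose peak exceeds the
    suggestive threshold in at least one map.  Returns the comparison frame
    and summary of :func:`compare_peaks`.
    """
    def peaks(scans, thr):
        frames = [find_peaks(s, thr, coverage) for s in scans]
        return pd.concat(frames, ignore_index=True)

    po = peaks(old_scans, suggestive_old)
    pn = peaks(new_scans, suggestive_new)
    either = set()
    for df in (po, pn):
        det = df.loc[df["detected"], ["phenotype", "model", "chromosome"]]
        either.update(map(tuple, det.to_numpy()))
    def restrict(df):
        key = list(map(tuple, df[["phenotype", "model", "chromosome"]].to_numpy()))
        df = df.loc[[k in either for k in key]].copy()
        df.loc[~df["detected"], "peak_cm"] = np.nan
        return df.drop(columns=["detected"])

    return compare_peaks(restrict(po), restrict(pn), shift_threshold_cm)
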