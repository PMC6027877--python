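"""Synthetic heterogeneous-stock (HS) cohorts with known recombination truth.

The simulator emulates the mapping resource behind the revised rat genetic
map: an HS colony descended from eight inbred founder strains, genotyped on a
dense biallelic panel, organised in nuclear families whose final-generation
offspring contribute two informative meioses each (one per parent).  Every
stage of the downstream pipeline (QC, map estimation, map cleaning) can be
validated against the recorded truth: founder haplotypes, per-gamete
crossover positions, corrupted calls and physically displaced markers.

The default crossover model is a sex-specific Poisson process on the cM scale
(no interference, no obligate chiasma), the generative inverse of the Haldane
mapping function used by the estimator.  A gamma-renewal interference model is
available behind the ``interference_nu`` flag of :func:`draw_gamete`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    MALE,
    FEMALE,
    CohortTruth,
    GenotypeTable,
    HsmapError,
    MarkerPanel,
    Pedigree,
    TrueRecombinationMap,
)

__all__ = [
    "FounderHaplotypes",
    "make_marker_panel",
    "build_hs_pedigree",
    "simulate_founder_haplotypes",
    "draw_gamete",
    "simulate_cohort",
    "corrupt_marker_positions",
]


def make_marker_panel(chromosome_lengths_bp, spacing_bp, seed: int) -> MarkerPanel:
    """Draw a biallelic marker panel with median inter-marker spacing ~= ``spacing_bp``.

    ``spacing_bp`` may be one integer for the whole genome or a dict per
    chromosome.  Gaps are uniform on ``[0.5, 1.5] * spacing_bp`` so both the
    mean and the median adjacent gap equal the requested spacing.
    Deterministic under a fixed seed.
    """
    spacings = {
        chrom: int(spacing_bp[chrom] if isinstance(spacing_bp, dict) else spacing_bp)
        for chrom in chromosome_lengths_bp
    }
    for chrom, L in chromosome_lengths_bp.items():
        if spacings[chrom] <= 0:
            raise HsmapError("spacing must be positive")
        if int(L) <= spacings[chrom]:
            raise HsmapError(f"chromosome {chrom} not longer than the spacing")
    rng = np.random.default_rng(seed)
    ids, chroms, pos = [], [], []
    for chrom, L in chromosome_lengths_bp.items():
        L = int(L)
        sp = spacings[chrom]
        n_max = int(np.ceil(L / (0.5 * sp))) + 2
        gaps = rng.integers(max(1, sp // 2), sp + sp // 2 + 1, size=n_max)
        p = np.cumsum(gaps) - gaps[0] + 1 + int(rng.integers(0, sp // 2 + 1))
        p = p[p <= L]
        ids.extend(f"{chrom}_{k:06d}" for k in range(p.size))
        chroms.extend([chrom] * p.size)
        pos.append(p)
    alleles = np.empty((len(ids), 2), dtype=object)
    alleles[:, 0] = "A"
    alleles[:, 1] = "B"
    return MarkerPanel(np.array(ids, object), np.array(chroms, object), np.concatenate(pos), alleles)


def build_hs_pedigree(
    n_families: int,
    offspring_per_family: float,
    n_founder_strains: int = 8,
    seed: int = 0,
) -> Pedigree:
    """Three-generation HS-style pedigree.

    Each family has four inbred founder grandparents (strains sampled without
    replacement), one sire and one dam bred from them, and a sibship of
    final-generation offspring.  ``offspring_per_family`` may be fractional:
    the rounded total is spread across families so that, e.g., 65 families at
    6.7 offspring yield 436 offspring ~ 870 informative meioses (two per
    final-generation offspring).  Founder rows carry their strain index in the
    ``strain`` column.
    """
    if n_families < 1:
        raise HsmapError("pedigree needs at least one family")
    if n_founder_strains < 2:
        raise HsmapError("need at least two founder strains")
    rng = np.random.default_rng(seed)
    total = int(round(n_families * offspring_per_family))
    if total < n_families:
        raise HsmapError("fewer offspring than families")
    base, extra = divmod(total, n_families)
    rows = []
    for f in range(n_families):
        fam = f"fam{f:03d}"
        strains = rng.choice(n_founder_strains, size=min(4, n_founder_strains), replace=False)
        if strains.size < 4:  # few strains: reuse across grandparent pairs
            strains = rng.choice(n_founder_strains, size=4, replace=True)
        gp = [f"{fam}_g{k}" for k in range(4)]
        for k, (gid, sx) in enumerate(zip(gp, (MALE, FEMALE, MALE, FEMALE))):
            rows.append((gid, None, None, sx, fam, 0, int(strains[k])))
        sire, dam = f"{fam}_sire", f"{fam}_dam"
        rows.append((sire, gp[0], gp[1], MALE, fam, 1, None))
        rows.append((dam, gp[2], gp[3], FEMALE, fam, 1, None))
        n_off = base + (1 if f < extra else 0)
        for j in range(n_off):
            sx = MALE if rng.random() < 0.5 else FEMALE
            rows.append((f"{fam}_o{j:02d}", sire, dam, sx, fam, 2, None))
    df = pd.DataFrame(
        rows,
        columns=["individual_id", "sire_id", "dam_id", "sex", "family_id", "generation", "strain"],
    )
    return Pedigree(df)


@dataclass
class FounderHaplotypes:
    """One homozygous haplotype per inbred founder strain on a marker panel."""

    panel: MarkerPanel
    haplotypes: np.ndarray  # int8 (n_strains, n_markers), allele-B indicator

    @property
    def n_strains(self) -> int:
        return int(self.haplotypes.shape[0])


def simulate_founder_haplotypes(
    panel: MarkerPanel,
    n_strains: int = 8,
    polymorphic_fraction: float = 0.85,
    seed: int = 0,
) -> FounderHaplotypes:
    """Inbred founder strain haplotypes; a set fraction of markers polymorphic.

    Polymorphic markers carry the B allele in ``k`` of the strains with ``k``
    uniform on ``1..n_strains-1``; the remainder are monomorphic (to exercise
    QC).  Each strain is fully homozygous, so its two chromosome copies are a
    single haplotype.
    """
    if n_strains < 2:
        raise HsmapError("need at least two strains")
    if not (0.0 <= polymorphic_fraction <= 1.0):
        raise HsmapError("polymorphic_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = panel.n_markers
    hap = np.zeros((n_strains, m), dtype=np.int8)
    poly = rng.random(m) < polymorphic_fraction
    k = rng.integers(1, n_strains, size=m)
    # monomorphic markers may be fixed for either allele
    mono_b = (~poly) & (rng.random(m) < 0.5)
    hap[:, mono_b] = 1
    for j in np.nonzero(poly)[0]:
        carriers = rng.choice(n_strains, size=int(k[j]), replace=False)
        hap[carriers, j] = 1
    return FounderHaplotypes(panel, hap)


def _draw_crossover_bps(total_cm: float, rng, interference_nu: float | None) -> np.ndarray:
    """Crossover positions on the cM scale of one chromosome."""
    if total_cm <= 0:
        return np.empty(0)
    if interference_nu is None:
        n = rng.poisson(total_cm / 100.0)
        return np.sort(rng.uniform(0.0, total_cm, size=n))
    # gamma-renewal (stationary) chiasma interference on the cM scale
    shape = float(interference_nu)
    scale = 100.0 / shape
    pts, t = [], float(rng.gamma(shape, scale)) * rng.random()  # stationary start
    while t < total_cm:
        pts.append(t)
        t += rng.gamma(shape, scale)
    return np.asarray(pts)


def draw_gamete(
    parent_haplotypes,
    true_map: TrueRecombinationMap,
    parent_sex: str,
    rng,
    panel: MarkerPanel | None = None,
    interference_nu: float | None = None,
    _chrom_slices: dict | None = None,
):
    """Recombine a parent's two haplotypes into one transmitted gamete.

    ``parent_haplotypes`` is a pair of allele arrays over the full panel.
    Crossover counts per chromosome follow Poisson(total_cM/100) for the
    parent's sex (or a gamma-renewal process when ``interference_nu`` is
    given); positions are uniform on the cM scale and mapped to bp through the
    inverse of the truth map.  Returns ``(gamete, crossovers)`` with
    ``crossovers`` a dict chromosome -> bp array.
    """
    hap_a, hap_b = parent_haplotypes
    if panel is None:
        raise HsmapError("draw_gamete requires the marker panel")
    if _chrom_slices is None:
        _chrom_slices = {c: panel.chrom_slice(c) for c in true_map.chromosomes}
    gamete = np.empty(panel.n_markers, dtype=np.int8)
    crossovers = {}
    for chrom in true_map.chromosomes:
        sl = _chrom_slices[chrom]
        cm_total = true_map.total_cm(chrom, parent_sex)
        xo_cm = _draw_crossover_bps(cm_total, rng, interference_nu)
        xo_bp = np.sort(true_map.bp_at(chrom, parent_sex, xo_cm)) if xo_cm.size else np.empty(0)
        start = int(rng.integers(0, 2))
        pos = panel.position_bp[sl]
        if xo_bp.size:
            seg = np.searchsorted(xo_bp, pos)
            sel = (start + seg) % 2
            gamete[sl] = np.where(sel == 0, hap_a[sl], hap_b[sl])
        else:
            gamete[sl] = hap_a[sl] if start == 0 else hap_b[sl]
        crossovers[chrom] = xo_bp
    return gamete, crossovers


def simulate_cohort(
    pedigree: Pedigree,
    founders: FounderHaplotypes,
    true_map: TrueRecombinationMap,
    error_rate: float = 0.002,
    missing_rate: float = 0.02,
    mendel_bad_marker_fraction: float = 0.02,
    bad_marker_error_rate: float = 0.05,
    seed: int = 0,
    interference_nu: float | None = None,
    x_chromosome=None,
):
    """Genotype a pedigree by gamete transmission, then corrupt calls.

    Offspring genotypes are the union of one gamete from each parent.  A
    ``mendel_bad_marker_fraction`` of markers receive an inflated per-call
    error rate so that their cohort Mendelian-error rate exceeds the 2% QC
    threshold with high probability; all remaining calls are flipped at
    ``error_rate`` (symmetric single-allele swap) and dropped to missing at
    ``missing_rate``.  Naming an ``x_chromosome`` switches it to
    hemizygous-male mode: sires transmit that chromosome whole (one of their
    two copies, no crossovers), so only female meioses recombine it.
    Returns ``(GenotypeTable, CohortTruth)``.
    """
    for rate in (error_rate, missing_rate, mendel_bad_marker_fraction, bad_marker_error_rate):
        if not (0.0 <= rate <= 1.0):
            raise HsmapError("rates must lie in [0, 1]")
    panel = founders.panel
    rng = np.random.default_rng(seed)
    ped = pedigree.table.sort_values(["generation", "individual_id"], kind="stable")
    individuals = list(ped["individual_id"])
    slices = {c: panel.chrom_slice(c) for c in true_map.chromosomes}
    n, m = len(individuals), panel.n_markers
    haplos = {}
    dosage = np.empty((n, m), dtype=np.int8)
    crossovers = {}
    founder_strains = {}
    row_of = {ind: i for i, ind in enumerate(individuals)}
    for _, r in ped.iterrows():
        ind = r["individual_id"]
        if pd.isna(r["sire_id"]):
            strain = r.get("strain")
            if strain is None or (isinstance(strain, float) and np.isnan(strain)):
                raise HsmapError(f"founder {ind!r} has no strain assignment")
            strain = int(strain)
            if strain >= founders.n_strains:
                raise HsmapError(f"founder {ind!r} references unknown strain {strain}")
            h = founders.haplotypes[strain]
            haplos[ind] = (h, h)
            founder_strains[ind] = strain
        else:
            sire, dam = r["sire_id"], r["dam_id"]
            if sire not in haplos or dam not in haplos:
                raise HsmapError(f"pedigree parent of {ind!r} not simulated")
            gam_s, xo_s = draw_gamete(haplos[sire], true_map, MALE, rng, panel, interference_nu, _chrom_slices=slices)
            if x_chromosome is not None and x_chromosome in slices:
                sl_x = slices[x_chromosome]
                pick = haplos[sire][int(rng.integers(0, 2))]
                gam_s[sl_x] = pick[sl_x]
                xo_s[x_chromosome] = np.empty(0)
            gam_d, xo_d = draw_gamete(haplos[dam], true_map, FEMALE, rng, panel, interference_nu, _chrom_slices=slices)
            haplos[ind] = (gam_s, gam_d)
            for chrom, bps in xo_s.items():
                crossovers[(ind, "sire", chrom)] = bps
            for chrom, bps in xo_d.items():
                crossovers[(ind, "dam", chrom)] = bps
        hs, hd = haplos[ind]
        dosage[row_of[ind]] = hs + hd

    # per-call corruption
    p_err = np.full(m, error_rate)
    n_bad = int(round(mendel_bad_marker_fraction * m))
    bad_idx = rng.choice(m, size=n_bad, replace=False) if n_bad else np.empty(0, np.int64)
    p_err[bad_idx] = bad_marker_error_rate
    err_mask = rng.random((n, m)) < p_err[None, :]
    if err_mask.any():
        rows, cols = np.nonzero(err_mask)
        g = dosage[rows, cols]
        up = rng.random(rows.size) < 0.5
        new = np.where(g == 0, 1, np.where(g == 2, 1, np.where(up, 0, 2)))
        dosage[rows, cols] = new.astype(np.int8)
    miss_mask = rng.random((n, m)) < missing_rate
    dosage[miss_mask] = MISSING

    truth = CohortTruth(
        crossovers=crossovers,
        error_calls=np.column_stack(np.nonzero(err_mask)) if err_mask.any() else np.empty((0, 2), np.int64),
        missing_calls=np.column_stack(np.nonzero(miss_mask)) if miss_mask.any() else np.empty((0, 2), np.int64),
        founder_strains=founder_strains,
    )
    truth.bad_markers = list(panel.marker_id[np.sort(bad_idx)]) if n_bad else []
    gt = GenotypeTable(individuals, panel, dosage)
    return gt, truth


def corrupt_marker_positions(
    panel: MarkerPanel,
    fraction: float,
    min_shift_bp: int,
    seed: int,
    chromosome_lengths_bp=None,
):
    """Displace a minority of markers' physical positions (assembly errors).

    Selected markers move at least ``min_shift_bp`` within their chromosome
    (direction and magnitude random; off-chromosome draws are redrawn); the
    genetic data keyed by marker id is unchanged.  Returns the re-sorted panel
    and the displaced marker ids — the ground truth for cleaning tests.
    """
    if not (0.0 <= fraction < 0.2):
        raise HsmapError("displaced fraction must be a minority (< 0.2)")
    rng = np.random.default_rng(seed)
    pos = panel.position_bp.copy()
    if chromosome_lengths_bp is None:
        chromosome_lengths_bp = {
            c: int(panel.position_bp[panel.chrom_slice(c)][-1]) for c in panel.chromosomes
        }
    n_move = int(round(fraction * panel.n_markers))
    if n_move == 0:
        return panel, []
    idx = np.sort(rng.choice(panel.n_markers, size=n_move, replace=False))
    displaced = list(panel.marker_id[idx])
    for j in idx:
        chrom = panel.chromosome[j]
        L = int(chromosome_lengths_bp[chrom])
        if L <= 2 * min_shift_bp and min_shift_bp >= L:
            raise HsmapError(f"shift {min_shift_bp} does not fit chromosome {chrom}")
        for _ in range(1000):
            mag = int(rng.integers(min_shift_bp, 2 * min_shift_bp + 1))
            new = pos[j] + (mag if rng.random() < 0.5 else -mag)
            if 1 <= new <= L:
                pos[j] = new
                break
        else:
            raise HsmapError(f"could not displace marker {panel.marker_id[j]}")
    # resolve (rare) position collisions, then re-sort within chromosomes
    order = []
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        p = pos[sl]
        while len(np.unique(p)) != p.size:
            _, first = np.unique(p, return_index=True)
            dup = np.setdiff1d(np.arange(p.size), first)
            p[dup] += 1
        pos[sl] = p
        order.append(np.arange(sl.start, sl.stop)[np.argsort(p, kind="stable")])
    order = np.concatenate(order)
    new_panel = MarkerPanel(
        panel.marker_id[order], panel.chromosome[order], pos[order], panel.alleles[order]
    )
    return new_panel, displaced
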