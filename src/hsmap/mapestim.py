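"""Sex-specific genetic-map estimation from pedigree genotypes.

Marker order is taken from physical positions (no re-ordering).  The stages
are:

1. :func:`call_parents` — logically forced imputation of missing parental
   genotypes from grandparents, the other parent and the offspring.
2. :func:`distortion_filter` — removal of markers whose pooled offspring
   genotype counts deviate from Mendelian expectation (chi-square).
3. :func:`phase_and_extract` — per-parent phasing of heterozygous markers by
   minimum-recombination chain extension (exhaustive for small marker sets),
   yielding per-meiosis founder-origin sequences.
4. :func:`interval_recfrac` — per-interval recombination fractions for one
   transmitting-parent sex, via a span-based coverage estimator: each meiosis
   informs every interval between its consecutive resolved markers, and each
   crossover event is assigned fractionally (by bp) to the intervals of its
   span.  Genotyping-error tolerance comes from a minimum-support filter on
   origin runs, with a Poisson-model correction for the true close double
   crossovers that the filter hides (see docs/methods.md).
5. :func:`assemble_map` — cumulative cM tracks (male, female, averaged) plus
   a per-marker placement-discordance diagnostic used by the map cleaner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genoqc import _MENDEL_INCOMPATIBLE
from .types import (
    MALE,
    FEMALE,
    SEXES,
    GeneticMap,
    GenotypeTable,
    HsmapError,
    MarkerPanel,
    Pedigree,
)

__all__ = [
    "MeiosisSet",
    "IntervalEstimate",
    "call_parents",
    "distortion_filter",
    "phase_and_extract",
    "interval_recfrac",
    "map_distance",
    "inverse_map_distance",
    "assemble_map",
    "replicate_consensus",
    "estimate_map",
]

#: crossover intensity on the cM scale (events per cM per meiosis)
_LAMBDA = 0.01


# ---------------------------------------------------------------------------
# mapping functions

def map_distance(r, mapping_function: str = "haldane"):
    """Convert recombination fraction(s) to cM.

    Haldane: ``-50 ln(1-2r)`` (no interference); Kosambi:
    ``25 ln((1+2r)/(1-2r))``.  Requires ``0 <= r < 0.5``.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise HsmapError("recombination fraction must lie in [0, 0.5)")
    if mapping_function == "haldane":
        d = -50.0 * np.log1p(-2.0 * r)
    elif mapping_function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    else:
        raise HsmapError(f"unknown mapping function {mapping_function!r}")
    return d if d.shape else float(d)


def inverse_map_distance(cm, mapping_function: str = "haldane"):
    """Convert cM to recombination fraction (inverse of :func:`map_distance`)."""
    cm = np.asarray(cm, dtype=np.float64)
    if np.any(cm < 0):
        raise HsmapError("distance must be non-negative")
    if mapping_function == "haldane":
        r = 0.5 * (1.0 - np.exp(-cm / 50.0))
    elif mapping_function == "kosambi":
        r = 0.5 * np.tanh(cm / 50.0)
    else:
        raise HsmapError(f"unknown mapping function {mapping_function!r}")
    return r if r.shape else float(r)


# ---------------------------------------------------------------------------
# parental genotype calling

def _parent_child_compatible(gp_s, gp_d, child) -> bool:
    """Can ``child`` dosage arise from parents with dosages gp_s/gp_d (-1 unknown)?"""
    if gp_s >= 0 and gp_d >= 0:
        return not _MENDEL_INCOMPATIBLE[gp_s, gp_d, child]
    for gp, known in ((gp_s, gp_s >= 0), (gp_d, gp_d >= 0)):
        if known:
            if (gp == 0 and child == 2) or (gp == 2 and child == 0):
                return False
    return True


def call_parents(gt: GenotypeTable, ped: Pedigree) -> GenotypeTable:
    """Impute missing parental genotypes only where logically forced.

    A missing parental call is filled in when exactly one dosage is
    compatible with the non-missing genotypes of the parent's own parents,
    its mate and all their offspring; a marker admitting *no* compatible
    value for some family is flagged (``gt.contradicted`` id list) and left
    missing.  Complete input is returned unchanged.
    """
    dosage = gt.dosage.copy()
    contradicted: set = set()
    trios = ped.trios()
    parent_of = dict(zip(ped.table["individual_id"], zip(ped.table["sire_id"], ped.table["dam_id"])))
    for (sire, dam), group in trios.groupby(["sire_id", "dam_id"], sort=False):
        if not (gt.has(sire) and gt.has(dam)):
            continue
        kids = [k for k in group["individual_id"] if gt.has(k)]
        if not kids:
            continue
        si, di = gt.row_index([sire])[0], gt.row_index([dam])[0]
        O = dosage[gt.row_index(kids)]
        S, D = dosage[si], dosage[di]
        targets = np.nonzero((S < 0) | (D < 0))[0]
        if targets.size == 0:
            continue
        gp_rows = {}
        for pid in (sire, dam):
            gs, gd = parent_of.get(pid, (None, None))
            gp_rows[pid] = (
                dosage[gt.row_index([gs])[0]] if gs is not None and not pd.isna(gs) and gt.has(gs) else None,
                dosage[gt.row_index([gd])[0]] if gd is not None and not pd.isna(gd) and gt.has(gd) else None,
            )
        for j in targets:
            cand_s = [S[j]] if S[j] >= 0 else [0, 1, 2]
            cand_d = [D[j]] if D[j] >= 0 else [0, 1, 2]
            ok_pairs = []
            for cs in cand_s:
                gs, gd = gp_rows[sire]
                if not _parent_child_compatible(
                    gs[j] if gs is not None else -1, gd[j] if gd is not None else -1, cs
                ):
                    continue
                for cd in cand_d:
                    gs2, gd2 = gp_rows[dam]
                    if not _parent_child_compatible(
                        gs2[j] if gs2 is not None else -1, gd2[j] if gd2 is not None else -1, cd
                    ):
                        continue
                    kid_calls = O[:, j]
                    kid_calls = kid_calls[kid_calls >= 0]
                    if kid_calls.size and _MENDEL_INCOMPATIBLE[cs, cd, kid_calls].any():
                        continue
                    ok_pairs.append((cs, cd))
            if not ok_pairs:
                contradicted.add(gt.panel.marker_id[j])
                continue
            if S[j] < 0:
                vals = {cs for cs, _ in ok_pairs}
                if len(vals) == 1:
                    dosage[si, j] = vals.pop()
            if D[j] < 0:
                vals = {cd for _, cd in ok_pairs}
                if len(vals) == 1:
                    dosage[di, j] = vals.pop()
    out = GenotypeTable(list(gt.individuals), gt.panel, dosage)
    out.contradicted = sorted(contradicted)
    return out


# ---------------------------------------------------------------------------
# segregation distortion

def distortion_filter(
    gt: GenotypeTable,
    ped: Pedigree,
    p_min: float = 0.001,
    min_informative: int = 10,
):
    """Remove markers whose pooled offspring counts defy Mendelian expectation.

    Expected genotype probabilities per offspring follow from its parents'
    dosages (each parent transmits its B allele with probability dosage/2);
    observed offspring genotype counts are tested against the pooled expected
    counts with a Pearson chi-square (zero-expectation cells are excluded
    from the statistic; their observed counts are Mendelian errors handled
    upstream).  Markers with ``p < p_min`` are removed.  Markers with fewer
    than ``min_informative`` complete trios are retained untested.
    """
    trios = ped.trios()
    trios = trios[
        trios["individual_id"].map(gt.has) & trios["sire_id"].map(gt.has) & trios["dam_id"].map(gt.has)
    ]
    m = gt.panel.n_markers
    stat = np.zeros(m)
    pval = np.ones(m)
    n_inf = np.zeros(m, dtype=np.int64)
    if len(trios):
        o_rows = gt.row_index(trios["individual_id"])
        s_rows = gt.row_index(trios["sire_id"])
        d_rows = gt.row_index(trios["dam_id"])
        chunk = 4096
        for lo in range(0, m, chunk):
            sl = slice(lo, min(lo + chunk, m))
            O = gt.dosage[o_rows, sl].astype(np.float64)
            S = gt.dosage[s_rows, sl].astype(np.float64)
            D = gt.dosage[d_rows, sl].astype(np.float64)
            ok = (O >= 0) & (S >= 0) & (D >= 0)
            ps, dm = S / 2.0, D / 2.0
            e0 = np.where(ok, (1 - ps) * (1 - dm), 0.0).sum(axis=0)
            e1 = np.where(ok, ps * (1 - dm) + (1 - ps) * dm, 0.0).sum(axis=0)
            e2 = np.where(ok, ps * dm, 0.0).sum(axis=0)
            obs = np.stack([(ok & (O == g)).sum(axis=0) for g in range(3)]).astype(np.float64)
            exp = np.stack([e0, e1, e2])
            n_inf[sl] = ok.sum(axis=0)
            for j in range(exp.shape[1]):
                e, ob = exp[:, j], obs[:, j]
                keep = e > 1e-9
                if keep.sum() <= 1:
                    continue
                # zero-expectation cells drop out (their counts pool implicitly)
                ob = ob[keep]
                e = e[keep]
                s = float(((ob - e) ** 2 / e).sum())
                stat[lo + j] = s
                pval[lo + j] = stats.chi2.sf(s, df=keep.sum() - 1)
    testable = n_inf >= min_informative
    remove = testable & (pval < p_min)
    removed = list(gt.panel.marker_id[remove])
    out = gt.subset_markers(~remove)
    out.distortion_stat = pd.DataFrame(
        {"marker_id": gt.panel.marker_id, "chi2": stat, "p": pval, "n": n_inf}
    )
    return out, removed


# ---------------------------------------------------------------------------
# phasing and meiosis extraction

@dataclass
class MeiosisSet:
    """Per-meiosis founder-origin sequences on a fixed marker panel.

    For each meiosis (offspring, transmitting parent) and chromosome the set
    stores the chromosome-local indices of markers where transmission was
    resolved, the phased origin (0/1 = parental haplotype) at each, and a
    phase-segment id (spans never cross segment boundaries).  ``mismatch`` /
    ``core`` hold, per marker, the count of meioses whose origin at the
    marker disagrees with two agreeing resolved flanks, and the count of such
    informative flank configurations — the placement-discordance statistic.
    """

    panel: MarkerPanel
    offspring: list = field(default_factory=list)
    parent: list = field(default_factory=list)
    parent_sex: list = field(default_factory=list)
    data: dict = field(default_factory=dict)  # chrom -> list of (idx, origins, seg) or None
    mismatch: np.ndarray | None = None
    core: np.ndarray | None = None
    min_run_support: int = 3

    @property
    def n_meioses(self) -> int:
        return len(self.offspring)

    def of_sex(self, sex: str) -> np.ndarray:
        if sex not in SEXES:
            raise HsmapError(f"unknown sex {sex!r}")
        return np.array([s == sex for s in self.parent_sex])

    def count_events(self, sex: str | None = None) -> int:
        """Total crossover events over consecutive resolved markers."""
        which = np.ones(self.n_meioses, bool) if sex is None else self.of_sex(sex)
        total = 0
        for chrom, entries in self.data.items():
            for i in np.nonzero(which)[0]:
                ent = entries[i]
                if ent is None:
                    continue
                idx, org, seg = ent
                if idx.size < 2:
                    continue
                same = seg[1:] == seg[:-1]
                total += int(((org[1:] != org[:-1]) & same).sum())
        return total


def _resolve_transmissions(S, D, O):
    """Transmitted-allele matrix from one parent (rows = offspring).

    ``S`` is the transmitting parent's dosage, ``D`` the mate's, ``O`` the
    offspring matrix.  Entries are 0/1 (allele index) where determined and
    the parent is heterozygous, else -1.
    """
    k = O.shape[0]
    T = np.full(O.shape, -1, dtype=np.int8)
    het = S == 1
    if not het.any():
        return T
    Dm = np.broadcast_to(D, O.shape)
    # offspring homozygote: transmitted allele is that allele
    T = np.where(het & (O == 0) & (Dm != 2), 0, T)
    T = np.where(het & (O == 2) & (Dm != 0), 1, T)
    # offspring heterozygote: resolvable only when the mate is homozygous
    T = np.where(het & (O == 1) & (Dm == 0), 1, T)
    T = np.where(het & (O == 1) & (Dm == 2), 0, T)
    return T.astype(np.int8)


def _orient_exhaustive(Th):
    """Minimum-recombination orientation by exhaustive search (small panels)."""
    k, H = Th.shape
    res_rows = [np.nonzero(Th[i] >= 0)[0] for i in range(k)]
    best, best_orient = None, np.zeros(H, dtype=np.int8)
    for bits in itertools.product((0, 1), repeat=max(H - 1, 0)):
        orient = np.concatenate([[0], np.cumsum(np.asarray(bits, dtype=np.int8)) % 2]).astype(np.int8)
        total = 0
        for i in range(k):
            r = res_rows[i]
            if r.size < 2:
                continue
            o = Th[i, r] ^ orient[r]
            total += int((o[1:] != o[:-1]).sum())
        if best is None or total < best:
            best, best_orient = total, orient
    return best_orient, []


def _orient_greedy(Th, max_switch_iters: int = 25):
    """Sequential minimum-recombination chain phasing with switch cleanup.

    Columns are processed left to right; each column's orientation is set by
    majority vote of the meioses resolved there against their last phased
    origin (ties extend the previous orientation).  A vectorised cleanup
    pass then removes residual phase switches — junctions where most
    spanning meioses would otherwise all "recombine" at once.
    """
    k, H = Th.shape
    orient = np.zeros(H, dtype=np.int8)
    # bit-packed rows: bit i of resmask[h] = row i resolved at column h
    weights = (1 << np.arange(k, dtype=np.uint64)).astype(np.uint64)
    resmask = ((Th >= 0).astype(np.uint64).T @ weights).tolist()
    valmask = ((Th == 1).astype(np.uint64).T @ weights).tolist()
    full = (1 << k) - 1
    # votes compare each meiosis's new origin with its *confirmed* origin — the
    # last value seen at two consecutive resolved markers — so an isolated
    # miscall cannot corrupt the phasing of later markers
    # Each column's phase is set by majority vote of the meioses resolved
    # there whose origin is *stable* (last two phased origins agree) — a
    # meiosis whose origin just changed abstains, because a one-marker-old
    # change is equally likely a miscall or a fresh crossover.  Columns with
    # no stable voter fall back to the tentative origins, then to the
    # previous column's orientation.  Phase is arbitrary per column, so a
    # lone qualifying voter decides.
    tentval = tenthave = confval = confhave = 0
    prev = 0
    void_cols = []
    for h in range(H):
        r = int(resmask[h])
        v = int(valmask[h])
        stable = confhave & tenthave & ~(tentval ^ confval)
        voters = r & stable
        if not voters:
            voters = r & tenthave
        o = prev
        if voters:
            n1 = ((v ^ tentval) & voters).bit_count()
            n0 = voters.bit_count() - n1
            # a column where every meiosis received the *same* allele can only
            # be real if every meiosis is on the same haplotype there; if the
            # current origins split substantially, the column is a miscalled
            # pseudo-heterozygous marker — void it for everyone
            vr = v & r
            if (vr == 0 or vr == r) and min(n1, n0) >= 2:
                void_cols.append(h)
                continue
            if n1 > n0:
                o = 1
            elif n0 > n1:
                o = 0
        orient[h] = o
        ov = v ^ (full if o else 0)
        confirm = r & tenthave & ~(ov ^ tentval)
        confval = (confval & ~confirm) | (ov & confirm)
        confhave |= confirm
        tentval = (tentval & ~r) | (ov & r)
        tenthave |= r
        prev = o
    # phase-switch cleanup: flip suffixes where spanning meioses agree on a jump
    res_rows = [np.nonzero(Th[i] >= 0)[0] for i in range(k)]
    if void_cols:
        res_rows = [r[~np.isin(r, void_cols)] for r in res_rows]
    covd = np.zeros(H + 1)
    for i in range(k):
        r = res_rows[i]
        if r.size < 2:
            continue
        np.add.at(covd, r[:-1], 1)
        np.add.at(covd, r[1:], -1)
    cov = np.cumsum(covd)[: H - 1]

    def total_events(orv):
        tot = 0
        for i in range(k):
            r = res_rows[i]
            if r.size < 2:
                continue
            o = Th[i, r] ^ orv[r]
            tot += int((o[1:] != o[:-1]).sum())
        return tot

    for _ in range(max_switch_iters):
        evd = np.zeros(H + 1)
        for i in range(k):
            r = res_rows[i]
            if r.size < 2:
                continue
            o = Th[i, r] ^ orient[r]
            hit = o[1:] != o[:-1]
            np.add.at(evd, r[:-1][hit], 1)
            np.add.at(evd, r[1:][hit], -1)
        ev = np.cumsum(evd)[: H - 1]
        cand = (ev >= 3) & (2 * ev > cov) & (cov > 0)
        if cand.any():
            g = int(np.nonzero(cand)[0][np.argmax(ev[cand])])
            orient[g + 1 :] ^= 1
            continue
        # mis-phased *regions* show as two nearby event pile-ups that a
        # single suffix flip cannot fix: trial-flip the enclosed columns
        hot = np.nonzero(ev >= 2)[0]
        base = total_events(orient)
        best = None
        for a_i in range(hot.size):
            for b_i in range(a_i + 1, hot.size):
                g1, g2 = int(hot[a_i]), int(hot[b_i])
                if g2 - g1 > 200:
                    break
                trial = orient.copy()
                trial[g1 + 1 : g2 + 1] ^= 1
                t = total_events(trial)
                if t < base and (best is None or t < best[0]):
                    best = (t, g1, g2)
        if best is None:
            break
        _, g1, g2 = best
        orient[g1 + 1 : g2 + 1] ^= 1
    return orient, void_cols


def phase_and_extract(
    gt: GenotypeTable,
    ped: Pedigree,
    panel: MarkerPanel | None = None,
    min_run_support: int = 3,
    exhaustive_max_markers: int = 12,
    min_parent_het_fraction: float = 0.01,
) -> MeiosisSet:
    """Phase each heterozygous parent and extract per-meiosis origin tracks.

    Phase is chosen to minimise total recombination events across the
    parent's meioses — exhaustively when the chromosome has at most
    ``exhaustive_max_markers`` heterozygous markers, otherwise by greedy
    chain extension with junction stitching and phase-switch cleanup.
    Origin runs supported by fewer than ``min_run_support`` resolved markers
    are voided as presumptive genotyping errors (set ``min_run_support=1``
    to disable).  Intervals where phase or transmission is ambiguous are
    simply absent from a meiosis's resolved set.  Parents heterozygous at
    fewer than ``min_parent_het_fraction`` of a chromosome's markers are
    uninformative there (their rare heterozygous calls are almost surely
    genotyping errors, e.g. in inbred founders) and contribute no meioses on
    that chromosome.
    """
    panel = panel or gt.panel
    if not np.array_equal(panel.marker_id, gt.panel.marker_id):
        raise HsmapError("panel does not match the genotype table")
    chroms = panel.chromosomes
    mset = MeiosisSet(panel=panel, data={c: [] for c in chroms}, min_run_support=min_run_support)
    M_stat = np.zeros(panel.n_markers, dtype=np.int64)
    core_stat = np.zeros(panel.n_markers, dtype=np.int64)

    trios = ped.trios()
    trios = trios[
        trios["individual_id"].map(gt.has) & trios["sire_id"].map(gt.has) & trios["dam_id"].map(gt.has)
    ]
    for role, sex in (("sire_id", MALE), ("dam_id", FEMALE)):
        mate_role = "dam_id" if role == "sire_id" else "sire_id"
        for (parent, mate), group in trios.groupby([role, mate_role], sort=False):
            kids = list(group["individual_id"])
            start = mset.n_meioses
            mset.offspring.extend(kids)
            mset.parent.extend([parent] * len(kids))
            mset.parent_sex.extend([sex] * len(kids))
            P = gt.row(parent)
            Q = gt.row(mate)
            O = gt.dosage[gt.row_index(kids)]
            for chrom in chroms:
                sl = panel.chrom_slice(chrom)
                T = _resolve_transmissions(P[sl], Q[sl], O[:, sl])
                cols = np.nonzero(P[sl] == 1)[0]
                entries = mset.data[chrom]
                while len(entries) < start:
                    entries.append(None)
                n_chrom = sl.stop - sl.start
                if cols.size < max(2, min_parent_het_fraction * n_chrom):
                    entries.extend([None] * len(kids))
                    continue
                Th = T[:, cols]
                if cols.size <= exhaustive_max_markers:
                    orient, void_cols = _orient_exhaustive(Th)
                else:
                    orient, void_cols = _orient_greedy(Th)
                for i in range(len(kids)):
                    r = np.nonzero(Th[i] >= 0)[0]
                    if void_cols:
                        r = r[~np.isin(r, void_cols)]
                    if r.size == 0:
                        entries.append(None)
                        continue
                    seg = np.zeros(r.size, dtype=np.int32)
                    o = (Th[i, r] ^ orient[r]).astype(np.uint8)
                    if r.size >= 3:
                        sm3 = (seg[:-2] == seg[1:-1]) & (seg[1:-1] == seg[2:])
                        flank = sm3 & (o[:-2] == o[2:])
                        gcols = sl.start + cols[r[1:-1][flank]]
                        core_stat[gcols] += 1
                        bad = flank & (o[1:-1] != o[:-2])
                        M_stat[sl.start + cols[r[1:-1][bad]]] += 1
                    if min_run_support > 1 and r.size:
                        bnd = np.concatenate([[True], (o[1:] != o[:-1]) | (seg[1:] != seg[:-1])])
                        run_id = np.cumsum(bnd) - 1
                        counts = np.bincount(run_id)
                        keep = counts[run_id] >= min_run_support
                        r, o, seg = r[keep], o[keep], seg[keep]
                    if r.size == 0:
                        entries.append(None)
                    else:
                        entries.append((cols[r].astype(np.int32), o, seg))
    for chrom in chroms:
        entries = mset.data[chrom]
        while len(entries) < mset.n_meioses:
            entries.append(None)
    mset.mismatch = M_stat
    mset.core = core_stat
    return mset


# ---------------------------------------------------------------------------
# interval estimates and map assembly

@dataclass
class IntervalEstimate:
    """Per-interval recombination estimates for one transmitting-parent sex."""

    sex: str
    mapping_function: str
    tables: dict  # chrom -> DataFrame(bp_left, bp_right, n, k, r, cm, uninformative)
    correction: dict  # chrom -> support-filter loss factor applied to cm

    def chrom_total_cm(self, chrom) -> float:
        return float(self.tables[chrom]["cm"].sum())

    def total_cm(self) -> float:
        return float(sum(self.chrom_total_cm(c) for c in self.tables))

    def cumulative(self, chrom) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.tables[chrom]["cm"].to_numpy())])

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for chrom, t in self.tables.items():
            f = t.copy()
            f.insert(0, "chromosome", chrom)
            f["sex"] = self.sex
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def _spans(entry):
    """Consecutive same-segment resolved pairs of one meiosis: (a, c, event)."""
    idx, org, seg = entry
    if idx.size < 2:
        return None
    sm = seg[1:] == seg[:-1]
    return idx[:-1][sm], idx[1:][sm], (org[1:] != org[:-1])[sm]


def interval_recfrac(
    meioses: MeiosisSet,
    sex: str,
    mapping_function: str = "haldane",
    support_correction: bool = True,
) -> IntervalEstimate:
    """Adjacent-marker recombination fractions from one sex's meioses.

    For every meiosis, each pair of consecutive resolved markers spans a run
    of adjacent-marker intervals: the meiosis counts toward the informative
    total ``n`` of every spanned interval, and a recombinant span contributes
    its single event to ``k`` fractionally, in proportion to interval bp
    length.  ``r = k/n``; intervals with ``n = 0`` are flagged uninformative
    and assigned 0 cM.  When ``support_correction`` is on, per-chromosome
    distances are scaled up by the expected fraction of crossovers hidden by
    the minimum-support run filter and span parity (Poisson model on the
    first-pass map).
    """
    which = np.nonzero(meioses.of_sex(sex))[0]
    panel = meioses.panel
    tables, corr = {}, {}
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        pos = panel.position_bp[sl]
        mloc = pos.size
        if mloc < 2:
            tables[chrom] = pd.DataFrame(
                columns=["bp_left", "bp_right", "n", "k", "r", "cm", "uninformative"]
            )
            corr[chrom] = 1.0
            continue
        nd = np.zeros(mloc + 1)
        kd = np.zeros(mloc + 1)
        entries = meioses.data[chrom]
        for i in which:
            ent = entries[i]
            if ent is None:
                continue
            sp = _spans(ent)
            if sp is None:
                continue
            a, c, hit = sp
            np.add.at(nd, a, 1.0)
            np.add.at(nd, c, -1.0)
            if hit.any():
                w = 1.0 / (pos[c[hit]] - pos[a[hit]])
                np.add.at(kd, a[hit], w)
                np.add.at(kd, c[hit], -w)
        n = np.cumsum(nd)[: mloc - 1]
        lens = np.diff(pos).astype(np.float64)
        k = np.cumsum(kd)[: mloc - 1] * lens
        uninf = n <= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(uninf, 0.0, k / np.maximum(n, 1.0))
        r = np.clip(r, 0.0, 0.499)
        d = np.asarray(map_distance(r, mapping_function), dtype=np.float64)
        factor = 1.0
        support = meioses.min_run_support
        if support_correction and k.sum() > 0:
            cum = np.concatenate([[0.0], np.cumsum(d)])
            lost = 0.0
            for i in which:
                ent = entries[i]
                if ent is None or ent[0].size < 2:
                    continue
                idx, _, seg = ent
                g = cum[idx]
                for s in np.unique(seg):
                    gs = g[seg == s]
                    if gs.size < 2:
                        continue
                    gaps = np.diff(gs)
                    # parity: even crossover counts within a span are invisible
                    lost += float(
                        (_LAMBDA * gaps - 0.5 * (1.0 - np.exp(-2.0 * _LAMBDA * gaps))).sum()
                    )
                    # close double crossovers hidden by the support filter:
                    # a pair whose middle run has < min_support resolved
                    # markers is voided (terminal-gap voiding removes
                    # coverage along with the event, so no term for it)
                    for t in range(1, support):
                        if gaps.size > t:
                            lost += 2.0 * _LAMBDA**2 * float((gaps[:-t] * gaps[t:]).sum())
            factor = 1.0 + lost / float(k.sum())
            d = d * factor
        tables[chrom] = pd.DataFrame(
            {
                "bp_left": pos[:-1],
                "bp_right": pos[1:],
                "n": n,
                "k": k,
                "r": r,
                "cm": d,
                "uninformative": uninf,
            }
        )
        corr[chrom] = factor
    return IntervalEstimate(sex=sex, mapping_function=mapping_function, tables=tables, correction=corr)


def _placement_offsets(meioses: MeiosisSet, alpha: float = 1e-3) -> np.ndarray:
    """Per-marker placement-discordance offsets (cM) from isolated mismatches.

    A marker whose origin calls disagree with agreeing resolved flanks far
    more often than the genome-wide background (Poisson tail < ``alpha``)
    receives a Haldane-scale offset — physically displaced markers show
    mismatch rates near the recombination fraction of their true-to-reported
    separation, concordant markers near the per-call error background.
    """
    M = meioses.mismatch.astype(np.float64)
    n = meioses.core.astype(np.float64)
    offs = np.zeros_like(M)
    usable = n > 0
    if not usable.any():
        return offs
    rate = np.zeros_like(M)
    rate[usable] = M[usable] / n[usable]
    eps = max(M[usable].sum() / n[usable].sum(), 1e-6)
    for _ in range(2):  # robustify the background against outliers
        bg = usable & (rate <= max(5 * eps, 0.02))
        if bg.any() and n[bg].sum() > 0:
            eps = max(M[bg].sum() / n[bg].sum(), 1e-6)
    flag = usable & (M >= 2) & (stats.poisson.sf(M - 1, n * eps) < alpha)
    r = np.clip(rate[flag], 0.0, 0.499)
    offs[flag] = -50.0 * np.log1p(-2.0 * r)
    return offs


def assemble_map(
    intervals_male: IntervalEstimate,
    intervals_female: IntervalEstimate,
    panel: MarkerPanel,
    meioses: MeiosisSet | None = None,
) -> GeneticMap:
    """Cumulative sex-specific and averaged cM tracks on the panel's markers.

    Each chromosome starts at 0 cM; the averaged track is the arithmetic mean
    of the sex tracks at every marker.  When a :class:`MeiosisSet` is given,
    per-marker placement-discordance offsets are attached (``offset_cm``) for
    the downstream residual filter.
    """
    frames = []
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        cm_m = intervals_male.cumulative(chrom)
        cm_f = intervals_female.cumulative(chrom)
        if cm_m.size != sl.stop - sl.start or cm_f.size != sl.stop - sl.start:
            raise HsmapError("interval tables do not match the panel")
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "marker_id": panel.marker_id[sl],
                    "position_bp": panel.position_bp[sl],
                    "cm_male": cm_m,
                    "cm_female": cm_f,
                    "cm_avg": (cm_m + cm_f) / 2.0,
                }
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    if meioses is not None:
        frame["offset_cm"] = _placement_offsets(meioses)
    return GeneticMap(frame)


def replicate_consensus(maps: list) -> GeneticMap:
    """Per-marker mean of replicate maps, monotonicity re-enforced isotonically."""
    from sklearn.isotonic import IsotonicRegression

    if not maps:
        raise HsmapError("no replicate maps")
    ref = maps[0].frame
    for gm in maps[1:]:
        if not np.array_equal(gm.frame["marker_id"].to_numpy(), ref["marker_id"].to_numpy()):
            raise HsmapError("replicate maps cover different marker sets")
    out = ref.copy()
    for col in ("cm_male", "cm_female", "offset_cm"):
        out[col] = np.mean([gm.frame[col].to_numpy(float) for gm in maps], axis=0)
    gm_out = GeneticMap(out)
    for chrom in gm_out.chromosomes:
        mask = out["chromosome"] == chrom
        x = out.loc[mask, "position_bp"].to_numpy(float)
        for col in ("cm_male", "cm_female"):
            iso = IsotonicRegression(increasing=True)
            out.loc[mask, col] = iso.fit_transform(x, out.loc[mask, col].to_numpy(float))
    out["cm_avg"] = (out["cm_male"] + out["cm_female"]) / 2.0
    return GeneticMap(out)


def _interp_track(full_bp: np.ndarray, clean_bp: np.ndarray, clean_cm: np.ndarray) -> np.ndarray:
    out = np.interp(full_bp, clean_bp, clean_cm)
    return out


def estimate_map(
    gt: GenotypeTable,
    ped: Pedigree,
    mapping_function: str = "haldane",
    distortion_p_min: float = 0.001,
    replicates: int = 0,
    seed: int | None = None,
    x_chromosome=None,
):
    """Full estimation stage: parent calling, distortion filter, phasing, map.

    Estimation is two-pass: markers whose placement-discordance diagnostic
    fires in the first pass (errant or error-prone markers) are excluded
    from the second-pass backbone so they cannot distort the cumulative map;
    they re-enter the final map at their backbone-interpolated position plus
    their discordance offset, where the downstream residual filter judges
    them.  With ``replicates > 0``, family-level bootstrap replicates are
    averaged by :func:`replicate_consensus`.  Naming an ``x_chromosome``
    switches that chromosome to hemizygous-male mode: only the female map is
    estimated there (males carry one X and do not recombine it), the male
    track is zeroed and the averaged track equals the female one.
    Returns ``(GeneticMap, diagnostics)``.
    """
    gt = call_parents(gt, ped)
    gt, distorted = distortion_filter(gt, ped, p_min=distortion_p_min)
    mset0 = phase_and_extract(gt, ped)
    offsets = _placement_offsets(mset0)
    suspects = offsets > 0
    if suspects.any():
        gt_b = gt.subset_markers(~suspects)
        mset = phase_and_extract(gt_b, ped)
    else:
        gt_b = gt
        mset = mset0

    def one_map(ms):
        iv_m = interval_recfrac(ms, MALE, mapping_function)
        iv_f = interval_recfrac(ms, FEMALE, mapping_function)
        backbone = assemble_map(iv_m, iv_f, gt_b.panel)
        if not suspects.any():
            out = backbone.frame.copy()
            out["offset_cm"] = offsets
            return GeneticMap(out)
        frames = []
        for chrom in gt.panel.chromosomes:
            sl = gt.panel.chrom_slice(chrom)
            sub = backbone.chrom(chrom)
            frames.append(
                pd.DataFrame(
                    {
                        "chromosome": chrom,
                        "marker_id": gt.panel.marker_id[sl],
                        "position_bp": gt.panel.position_bp[sl],
                        **{
                            col: _interp_track(
                                gt.panel.position_bp[sl].astype(float),
                                sub["position_bp"].to_numpy(float),
                                sub[col].to_numpy(float),
                            )
                            for col in ("cm_male", "cm_female", "cm_avg")
                        },
                        "offset_cm": offsets[sl],
                    }
                )
            )
        return GeneticMap(pd.concat(frames, ignore_index=True))

    if replicates > 0:
        rng = np.random.default_rng(seed)
        fam_of = dict(zip(ped.table["individual_id"], ped.table["family_id"]))
        fams = np.array([fam_of[o] for o in mset.offspring], dtype=object)
        unique_fams = np.unique(fams)
        reps = []
        for _ in range(replicates):
            pick = rng.choice(unique_fams, size=unique_fams.size, replace=True)
            rows = np.concatenate([np.nonzero(fams == f)[0] for f in pick])
            sub = MeiosisSet(
                panel=mset.panel,
                offspring=[mset.offspring[i] for i in rows],
                parent=[mset.parent[i] for i in rows],
                parent_sex=[mset.parent_sex[i] for i in rows],
                data={c: [mset.data[c][i] for i in rows] for c in mset.data},
                mismatch=mset.mismatch,
                core=mset.core,
            )
            reps.append(one_map(sub))
        gmap = replicate_consensus(reps)
    else:
        gmap = one_map(mset)
    if x_chromosome is not None and x_chromosome in gt.panel.chromosomes:
        xmask = (gmap.frame["chromosome"] == x_chromosome).to_numpy()
        gmap.frame.loc[xmask, "cm_male"] = 0.0
        gmap.frame.loc[xmask, "cm_avg"] = gmap.frame.loc[xmask, "cm_female"]
    diagnostics = {
        "removed_distorted": distorted,
        "n_meioses": mset.n_meioses,
        "meioses": mset,
        "intervals": {
            MALE: interval_recfrac(mset, MALE, mapping_function),
            FEMALE: interval_recfrac(mset, FEMALE, mapping_function),
        },
    }
    return gmap, diagnostics
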