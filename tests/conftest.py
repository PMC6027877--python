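import numpy as np
import pandas as pd
import pytest

from hsmap import simhs
from hsmap.types import GenotypeTable, MarkerPanel, Pedigree, TrueRecombinationMap


def make_panel(positions_by_chrom):
    """Panel from a dict chromosome -> bp position list."""
    ids, chroms, pos = [], [], []
    for chrom, ps in positions_by_chrom.items():
        for i, p in enumerate(ps):
            ids.append(f"{chrom}_m{i:03d}")
            chroms.append(chrom)
            pos.append(int(p))
    alleles = np.empty((len(ids), 2), dtype=object)
    alleles[:, 0] = "A"
    alleles[:, 1] = "B"
    return MarkerPanel(np.array(ids, object), np.array(chroms, object), np.array(pos), alleles)


def make_pedigree(rows):
    """Pedigree from (id, sire, dam, sex, family, generation) tuples."""
    df = pd.DataFrame(rows, columns=["individual_id", "sire_id", "dam_id", "sex", "family_id", "generation"])
    return Pedigree(df)


def nuclear_family(n_offspring, fam="f0", sexes=None):
    rows = [(f"{fam}_s", None, None, "male", fam, 0), (f"{fam}_d", None, None, "female", fam, 0)]
    for j in range(n_offspring):
        sx = sexes[j] if sexes else ("male" if j % 2 == 0 else "female")
        rows.append((f"{fam}_o{j}", f"{fam}_s", f"{fam}_d", sx, fam, 1))
    return make_pedigree(rows)


def table(ped, panel, dosages):
    """GenotypeTable from a dict individual -> dosage list."""
    inds = list(dosages)
    d = np.array([dosages[i] for i in inds], dtype=np.int8)
    return GenotypeTable(inds, panel, d)


@pytest.fixture(scope="session")
def hs_cohort():
    """A mid-sized simulated HS cohort with truth, shared across tests."""
    lengths = {"chr1": 80_000_000, "chr2": 50_000_000}
    cms = {"chr1": (60.0, 72.0), "chr2": (40.0, 46.0)}
    true_map = TrueRecombinationMap.from_lengths(lengths, cms)
    panel = simhs.make_marker_panel(lengths, 100_000, seed=11)
    ped = simhs.build_hs_pedigree(30, 6.0, 8, seed=12)
    founders = simhs.simulate_founder_haplotypes(panel, 8, 0.85, seed=13)
    gt, truth = simhs.simulate_cohort(ped, founders, true_map, seed=14)
    return dict(lengths=lengths, cms=cms, true_map=true_map, panel=panel, ped=ped,
                founders=founders, gt=gt, truth=truth)
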