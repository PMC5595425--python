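"""Shared fixtures: hand-constructed toy datasets and small helpers."""

import numpy as np
import pytest

from triopoo import MISSING, SnpInfo, TrioDataset


def make_dataset(genotypes, exposures=None, chrom="1"):
    """Build a TrioDataset from an (n_fam, 3, n_snps) int array."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n_fam, _, n_snps = geno.shape
    snps = [SnpInfo(f"s{j:02d}", chrom, 1000 * (j + 1), "A", "B") for j in range(n_snps)]
    families = [f"fam{i:02d}" for i in range(n_fam)]
    present = np.ones((n_fam, 3), dtype=bool)
    for mem in (0, 1):
        present[:, mem] = (geno[:, mem, :] != MISSING).any(axis=1)
    if exposures is None:
        exposures = np.full(n_fam, MISSING, dtype=np.int8)
    return TrioDataset(snps, families, geno, present,
                       np.asarray(exposures, dtype=np.int8))


def make_qc_toy_dataset():
    """20-SNP, 60-family dataset with hand-planted QC failures.

    * SNPs s03, s09, s18 fail the founder-MAF filter (a single het founder);
    * SNPs s06, s18 fail the call-rate filter (10/180 individuals missing);
    * s18 fails both, so 4 distinct SNPs are removed and 16 survive;
    * family fam00 is Mendelian-inconsistent at s00 and s01 (2/16 = 12.5%
      of retained SNPs, above the 5% family threshold) and is removed;
    * everything else passes: founder genotypes cycle through an
      (8 hom-alt, 44 het, 68 hom-ref) block pattern (MAF 0.25, close to
      Hardy-Weinberg proportions), children follow deterministic Mendelian
      transmissions, and adjacent SNPs use shifted patterns so no pair is
      in complete LD.
    """
    n_fam, n_snps = 60, 20
    base = np.array([2] * 8 + [1] * 44 + [0] * 68, dtype=np.int8)
    maf_fail = {3: 0, 9: 1, 18: 2}  # snp index -> index of the lone het founder
    miss_children = {6: range(0, 10), 18: range(20, 30)}

    geno = np.full((n_fam, 3, n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        if j in maf_fail:
            founders = np.zeros(2 * n_fam, dtype=np.int8)
            founders[maf_fail[j]] = 1
        else:
            founders = np.roll(base, 7 * j)
        for i in range(n_fam):
            m, f = int(founders[2 * i]), int(founders[2 * i + 1])
            xm = 1 if m == 2 else (1 if (m == 1 and (i + j) % 2 == 0) else 0)
            xp = 1 if f == 2 else (1 if (f == 1 and (i + j) % 3 == 0) else 0)
            geno[i, :, j] = (m, f, xm + xp)
    for j, kids in miss_children.items():
        geno[list(kids), 2, j] = MISSING
    # Mendelian inconsistencies for fam00 at the first two SNPs
    geno[0, :, 0] = (0, 0, 1)
    geno[0, :, 1] = (0, 0, 1)

    expected_removed_snps = {"s03", "s06", "s09", "s18"}
    expected_removed_families = {"fam00"}
    return make_dataset(geno), expected_removed_snps, expected_removed_families


@pytest.fixture
def qc_toy():
    return make_qc_toy_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(20170912)
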