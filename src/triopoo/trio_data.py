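"""Reading, encoding and validating case-parent trio genotype datasets.

Input is the text PLINK pedigree dialect: a ``.ped`` file with six leading
columns (family ID, individual ID, father ID, mother ID, sex, phenotype)
followed by two allele columns per SNP, and a ``.map`` file with four
columns (chromosome, SNP ID, genetic distance, base-pair position).  Each
family holds one affected proband (the case) and up to two genotyped
parents; families with one or both parents absent (duos / singletons) are
retained and handled downstream by likelihood marginalization.

Genotypes are encoded as the count of the *alternative* (minor) allele,
with the reference allele per SNP taken as the more frequent allele among
non-missing parental calls (ties broken by the lexicographically smaller
symbol).  Half-called genotypes are treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .likelihood import MISSING

__all__ = [
    "MISSING",
    "GenotypeCall",
    "SnpInfo",
    "TrioRecord",
    "TrioDataset",
    "PedigreeError",
    "read_ped_map",
    "write_ped_map",
    "read_exposure_table",
    "mendelian_consistent",
]

# member indices in the genotype array
MOTHER, FATHER, CHILD = 0, 1, 2


class PedigreeError(ValueError):
    """Malformed or internally inconsistent pedigree input."""


#: A genotype call is an int in {0, 1, 2} (alt-allele count) or MISSING.
GenotypeCall = int


@dataclass(frozen=True)
class SnpInfo:
    """Marker metadata; ``allele_ref`` is the major allele among founders."""

    snp_id: str
    chromosome: str
    position_bp: int
    allele_ref: str
    allele_alt: str

    def __post_init__(self):
        if self.position_bp < 1:
            raise ValueError(f"{self.snp_id}: position must be 1-based, >= 1")
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"{self.snp_id}: ref and alt allele must differ")


@dataclass(frozen=True)
class TrioRecord:
    """One family's calls at one SNP plus its exposure stratum."""

    family_id: str
    mother: GenotypeCall
    father: GenotypeCall
    child: GenotypeCall
    exposure: int = MISSING


@dataclass
class TrioDataset:
    """In-memory trio genotype dataset.

    genotypes
        int8 array of shape (n_families, 3, n_snps), member axis ordered
        (mother, father, child), MISSING = -1.
    present
        bool (n_families, 3); False where a member was absent from the
        pedigree (its genotype row is all MISSING).
    exposures
        int8 (n_families,), values {0, 1, MISSING}.
    """

    snps: list[SnpInfo]
    families: list[str]
    genotypes: np.ndarray
    present: np.ndarray
    exposures: np.ndarray
    member_iids: np.ndarray = None  # (n_fam, 3) str, for round-tripping
    member_sex: np.ndarray = None  # (n_fam, 3) int

    def __post_init__(self):
        n_fam, n_mem, n_snp = self.genotypes.shape
        assert n_mem == 3 and n_fam == len(self.families) and n_snp == len(self.snps)
        if self.member_iids is None:
            iids = np.empty((n_fam, 3), dtype=object)
            for i, fid in enumerate(self.families):
                iids[i] = [f"{fid}_m", f"{fid}_f", f"{fid}_c"]
            self.member_iids = iids
        if self.member_sex is None:
            self.member_sex = np.tile([2, 1, 0], (n_fam, 1))
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate SNP IDs in map")

    # -- basic shape -------------------------------------------------------
    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        try:
            return next(i for i, s in enumerate(self.snps) if s.snp_id == snp_id)
        except StopIteration:
            raise KeyError(f"unknown SNP ID {snp_id!r}") from None

    # -- views -------------------------------------------------------------
    def trios_at(self, snp) -> list[TrioRecord]:
        """Per-family records at one SNP (by ID or index)."""
        j = self.snp_index(snp) if isinstance(snp, str) else snp
        g = self.genotypes[:, :, j]
        return [
            TrioRecord(fid, int(g[i, MOTHER]), int(g[i, FATHER]), int(g[i, CHILD]),
                       int(self.exposures[i]))
            for i, fid in enumerate(self.families)
        ]

    def founder_dosages(self, snp) -> np.ndarray:
        """Parental alt-allele dosages at one SNP, one row per present
        parent (MISSING calls included as -1)."""
        j = self.snp_index(snp) if isinstance(snp, str) else snp
        out = []
        for mem in (MOTHER, FATHER):
            out.append(self.genotypes[self.present[:, mem], mem, j])
        return np.concatenate(out)

    # -- subsetting --------------------------------------------------------
    def subset_snps(self, keep: np.ndarray) -> "TrioDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return TrioDataset(
            [self.snps[i] for i in idx],
            list(self.families),
            self.genotypes[:, :, idx].copy(),
            self.present.copy(),
            self.exposures.copy(),
            self.member_iids.copy(),
            self.member_sex.copy(),
        )

    def drop_families(self, fids) -> "TrioDataset":
        fids = set(fids)
        keep = np.array([f not in fids for f in self.families])
        return TrioDataset(
            list(self.snps),
            [f for f in self.families if f not in fids],
            self.genotypes[keep].copy(),
            self.present[keep].copy(),
            self.exposures[keep].copy(),
            self.member_iids[keep].copy(),
            self.member_sex[keep].copy(),
        )

    def mask_member(self, family_idx: int, member: int) -> None:
        """Remove one parent in place (genotypes to MISSING, present False)."""
        self.genotypes[family_idx, member, :] = MISSING
        self.present[family_idx, member] = False

    def with_exposure(self, mapping) -> "TrioDataset":
        """Return a copy with exposures set from a {family ID: 0/1} mapping;
        families absent from the mapping get MISSING."""
        exp = np.full(self.n_families, MISSING, dtype=np.int8)
        for i, fid in enumerate(self.families):
            v = mapping.get(fid)
            if v is not None and not (isinstance(v, float) and np.isnan(v)):
                exp[i] = int(v)
        out = replace(self)
        out.exposures = exp
        return out


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------


def _transmissible(g: int):
    return {0: (0,), 1: (0, 1), 2: (1,)}[g]


def mendelian_consistent(mother: int, father: int, child: int) -> bool:
    """True iff some maternal x paternal transmission yields the child
    genotype; any MISSING member makes the triple vacuously consistent."""
    if MISSING in (mother, father, child):
        return True
    return any(
        xm + xp == child
        for xm in _transmissible(mother)
        for xp in _transmissible(father)
    )


# ---------------------------------------------------------------------------
# PED/MAP I/O
# ---------------------------------------------------------------------------


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PedigreeError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            try:
                pos = int(parts[3])
            except ValueError:
                raise PedigreeError(f"{map_path}:{ln}: bad base-pair position {parts[3]!r}")
            rows.append((parts[0], parts[1], pos))
    df = pd.DataFrame(rows, columns=["chrom", "snp_id", "pos"])
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise PedigreeError(f"{map_path}: duplicate SNP ID {dup!r}")
    # stable sort keeps file order within (chromosome, position) ties
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return df


def read_ped_map(ped_path, map_path) -> TrioDataset:
    """Parse a text .ped/.map pair into a :class:`TrioDataset`.

    Within each family, the affected individual with named parents is the
    proband; individuals with both parent IDs "0" are founders.  Families
    with more than one proband, or SNPs with more than two allele symbols,
    are rejected.
    """
    mapdf = _read_map(map_path)
    n_snps = len(mapdf)

    indivs = []  # (fid, iid, fat, mot, sex, phen, alleles)
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise PedigreeError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} columns "
                    f"(6 + 2 x {n_snps} SNPs), got {len(parts)}"
                )
            indivs.append((parts[0], parts[1], parts[2], parts[3], parts[4],
                           parts[5], parts[6:], ln))

    # map-file order was re-sorted; we read ped alleles in file order and
    # reorder to the sorted map below
    file_order = _read_map_file_order(map_path)
    perm = [file_order.index(sid) for sid in mapdf["snp_id"]]

    fam_order: list[str] = []
    fam_members: dict[str, list] = {}
    for rec in indivs:
        if rec[0] not in fam_members:
            fam_order.append(rec[0])
            fam_members[rec[0]] = []
        fam_members[rec[0]].append(rec)

    n_fam = len(fam_order)
    raw = np.empty((n_fam, 3, n_snps, 2), dtype=object)
    raw[:] = "0"
    present = np.zeros((n_fam, 3), dtype=bool)
    iids = np.full((n_fam, 3), "0", dtype=object)
    sexes = np.zeros((n_fam, 3), dtype=int)

    for i, fid in enumerate(fam_order):
        members = fam_members[fid]
        named_as_parent = {r[2] for r in members} | {r[3] for r in members}
        # proband: affected and not a parent of anyone (duos/singletons keep
        # one or both parent IDs at "0", so require only non-parent status)
        probands = [r for r in members if r[5] == "2" and r[1] not in named_as_parent]
        if len(probands) > 1:
            raise PedigreeError(f"family {fid}: more than one affected proband")
        if not probands:
            # fall back: a single non-founder individual
            named = [r for r in members
                     if (r[2] != "0" or r[3] != "0") and r[1] not in named_as_parent]
            if len(named) != 1:
                raise PedigreeError(f"family {fid}: no identifiable proband")
            probands = named
        child = probands[0]
        by_iid = {r[1]: r for r in members}
        slots = {CHILD: child, FATHER: by_iid.get(child[2]), MOTHER: by_iid.get(child[3])}
        for mem, rec in slots.items():
            if rec is None:
                continue
            present[i, mem] = True
            iids[i, mem] = rec[1]
            sexes[i, mem] = int(rec[4]) if rec[4].isdigit() else 0
            alle = rec[6]
            for jf in range(n_snps):
                raw[i, mem, jf, 0] = alle[2 * jf]
                raw[i, mem, jf, 1] = alle[2 * jf + 1]

    raw = raw[:, :, perm, :]

    snps = []
    geno = np.full((n_fam, 3, n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        sid = mapdf.loc[j, "snp_id"]
        symbols = raw[:, :, j, :]
        nonmiss = symbols[symbols != "0"]
        uniq = sorted(set(nonmiss.tolist()))
        if len(uniq) > 2:
            raise PedigreeError(f"SNP {sid}: more than two alleles observed: {uniq}")
        parent_alleles = raw[:, (MOTHER, FATHER), j, :]
        parent_alleles = parent_alleles[present[:, (MOTHER, FATHER)]]
        pa = parent_alleles[parent_alleles != "0"]
        source = pa if pa.size else nonmiss
        counts = pd.Series(source.tolist()).value_counts() if source.size else pd.Series(dtype=int)
        if len(uniq) == 0:
            ref, alt = "0", "."  # fully missing SNP; encoded all-MISSING
        elif len(uniq) == 1:
            ref, alt = uniq[0], "."
        else:
            cmax = max(counts.get(a, 0) for a in uniq)
            majors = sorted(a for a in uniq if counts.get(a, 0) == cmax)
            ref = majors[0]
            alt = next(a for a in uniq if a != ref)
        snps.append(SnpInfo(sid, str(mapdf.loc[j, "chrom"]), int(mapdf.loc[j, "pos"]), ref, alt))
        a = raw[:, :, j, :]
        half_or_missing = (a[..., 0] == "0") | (a[..., 1] == "0")
        g = ((a[..., 0] == alt).astype(np.int8) + (a[..., 1] == alt).astype(np.int8))
        g[half_or_missing] = MISSING
        g[~present] = MISSING
        geno[:, :, j] = g

    exposures = np.full(n_fam, MISSING, dtype=np.int8)
    return TrioDataset(snps, fam_order, geno, present, exposures, iids, sexes)


def _read_map_file_order(map_path) -> list[str]:
    order = []
    with open(map_path) as fh:
        for line in fh:
            if line.strip():
                order.append(line.split()[1])
    return order


def write_ped_map(dataset: TrioDataset, ped_path, map_path) -> None:
    """Write the dataset back to the text .ped/.map dialect.

    Genotypes round-trip exactly; heterozygotes are normalized to
    "ref alt" order and absent members are omitted.
    """
    with open(map_path, "w") as fh:
        for s in dataset.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\n")
    with open(ped_path, "w") as fh:
        for i, fid in enumerate(dataset.families):
            child_iid = dataset.member_iids[i, CHILD]
            for mem, (fat, mot, phen) in (
                (MOTHER, ("0", "0", "1")),
                (FATHER, ("0", "0", "1")),
                (CHILD, (dataset.member_iids[i, FATHER] if dataset.present[i, FATHER] else "0",
                         dataset.member_iids[i, MOTHER] if dataset.present[i, MOTHER] else "0",
                         "2")),
            ):
                if not dataset.present[i, mem]:
                    continue
                cols = [fid, str(dataset.member_iids[i, mem]), fat, mot,
                        str(int(dataset.member_sex[i, mem])), phen]
                for j, s in enumerate(dataset.snps):
                    g = dataset.genotypes[i, mem, j]
                    if g == MISSING:
                        cols += ["0", "0"]
                    elif g == 0:
                        cols += [s.allele_ref, s.allele_ref]
                    elif g == 1:
                        cols += [s.allele_ref, s.allele_alt]
                    else:
                        cols += [s.allele_alt, s.allele_alt]
                fh.write(" ".join(cols) + "\n")


def read_exposure_table(path) -> dict[str, int]:
    """Read the two-column exposure TSV (``FID<TAB>exposure``) into a
    mapping; exposure values other than 0/1 (NA, -9, blank) become MISSING
    when attached to a dataset."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if list(df.columns[:2]) != ["FID", "exposure"]:
        raise PedigreeError(
            f"{path}: expected header 'FID<TAB>exposure', got {list(df.columns)!r}"
        )
    out: dict[str, int] = {}
    for fid, v in zip(df["FID"], df["exposure"]):
        try:
            iv = int(v)
        except (TypeError, ValueError):
            continue
        if iv in (0, 1):
            out[str(fid)] = iv
    return out
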