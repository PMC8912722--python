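"""Data model and text I/O for diploid microsatellite genotype datasets.

Alleles are stored as integer fragment sizes exactly as genotyped; no binning
to repeat numbers is attempted.  Missing data use a single sentinel
(:data:`MISSING`); both allele slots of a locus are missing together or
present together (no half-calls).  Species is an attribute of the population,
not the individual: morphologically misidentified individuals are re-flagged
downstream, never re-homed here.

Supported formats: GenePop (.gen), the STRUCTURE two-rows-per-individual
table (.str), and a population metadata CSV with geography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing allele slot.
MISSING = -1


class GenotypeParseError(ValueError):
    """Raised on a malformed genotype file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes with population and species structure.

    Parameters
    ----------
    alleles
        Integer array of shape ``(n_individuals, n_loci, 2)`` of allele
        fragment sizes; :data:`MISSING` marks a missing slot.
    individual_ids
        Opaque per-individual identifiers.
    locus_names
        Locus labels, one per column.
    pop_of_individual
        Population label per individual.
    species_of_pop
        Mapping population label -> species label (exactly two species in
        scope).  May be empty until metadata is attached.
    geography
        Per-population ``latitude`` (deg N), ``longitude`` (deg E) and
        ``altitude`` (m a.s.l.), indexed by population label; optional.
    """

    alleles: np.ndarray
    individual_ids: list[str]
    locus_names: list[str]
    pop_of_individual: np.ndarray
    species_of_pop: dict[str, str] = field(default_factory=dict)
    geography: pd.DataFrame | None = None

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        self.pop_of_individual = np.asarray(self.pop_of_individual, dtype=object)

    # -- basic shape -----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pop_of_individual:
            seen.setdefault(p)
        return list(seen)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            if p in self.species_of_pop:
                seen.setdefault(self.species_of_pop[p])
        return list(seen)

    def species_of_individual(self) -> np.ndarray:
        return np.array([self.species_of_pop.get(p) for p in self.pop_of_individual], dtype=object)

    def individuals_of_pop(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.pop_of_individual == pop)

    def mask_for_species(self, species: str) -> np.ndarray:
        """Boolean mask selecting individuals whose population belongs to *species*."""
        return self.species_of_individual() == species

    def subset(self, individuals) -> "GenotypeDataset":
        idx = np.asarray(individuals)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        geo = self.geography
        return GenotypeDataset(
            alleles=self.alleles[idx].copy(),
            individual_ids=[self.individual_ids[i] for i in idx],
            locus_names=list(self.locus_names),
            pop_of_individual=self.pop_of_individual[idx].copy(),
            species_of_pop=dict(self.species_of_pop),
            geography=None if geo is None else geo.copy(),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raises ``ValueError`` on violation."""
        a = self.alleles
        if a.ndim != 3 or a.shape[2] != 2:
            raise ValueError(f"alleles must have shape (n, loci, 2), got {a.shape}")
        if len(self.individual_ids) != a.shape[0]:
            raise ValueError("individual_ids length does not match alleles")
        if len(self.locus_names) != a.shape[1]:
            raise ValueError("locus_names length does not match alleles")
        if len(self.pop_of_individual) != a.shape[0]:
            raise ValueError("pop_of_individual length does not match alleles")
        half = (a[:, :, 0] == MISSING) != (a[:, :, 1] == MISSING)
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-called genotype at individual {self.individual_ids[i]!r}, "
                f"locus {self.locus_names[l]!r}: both slots must be missing together"
            )
        present = a != MISSING
        if (a[present] <= 0).any():
            raise ValueError("allele sizes must be positive integers")
        if self.species_of_pop:
            missing_pops = [p for p in self.populations if p not in self.species_of_pop]
            if missing_pops:
                raise ValueError(f"populations without species assignment: {missing_pops}")

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, loci): True where the genotype is missing."""
        return self.alleles[:, :, 0] == MISSING


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def read_genepop(path, pop_names: list[str] | None = None) -> GenotypeDataset:
    """Read a GenePop file.

    Locus names come from the header (one per line, or comma-separated on a
    single line); populations are delimited by ``POP`` lines, in file order.
    Labels come from *pop_names* when given; otherwise, when every block's
    individual ids share a prefix before the last underscore (the convention
    this package writes), those prefixes are used, falling back to ``pop1``,
    ``pop2``, ...  Allele codes are 2 or 3 digits per allele; ``00``/``000``
    is missing.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenotypeParseError("empty file", 1)

    def is_pop(line: str) -> bool:
        return line.strip().lower() == "pop"

    # header: title line then locus names until first POP
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not is_pop(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenotypeParseError("no POP separator found", len(lines))
    if not locus_names:
        raise GenotypeParseError("no locus names in header", 2)

    ids: list[str] = []
    blocks: list[int] = []
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    block_count = 0
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if is_pop(line):
            if pop_idx > 0 and block_count == 0:
                raise GenotypeParseError("empty population block", lineno + 1)
            pop_idx += 1
            if pop_names is not None and pop_idx > len(pop_names):
                raise GenotypeParseError("more POP blocks than pop_names", lineno + 1)
            block_count = 0
            continue
        if "," not in line:
            raise GenotypeParseError("expected 'id , genotypes'", lineno + 1)
        ind_id, geno_part = line.split(",", 1)
        codes = geno_part.split()
        if len(codes) != len(locus_names):
            raise GenotypeParseError(
                f"expected {len(locus_names)} genotypes, got {len(codes)}", lineno + 1
            )
        genos: list[tuple[int, int]] = []
        for code in codes:
            if len(code) not in (4, 6) or not code.isdigit():
                raise GenotypeParseError(
                    f"genotype code {code!r} must be 4 or 6 digits", lineno + 1
                )
            w = len(code) // 2
            a1, a2 = int(code[:w]), int(code[w:])
            if (a1 == 0) != (a2 == 0):
                raise GenotypeParseError(
                    f"half-missing genotype {code!r} not allowed", lineno + 1
                )
            genos.append((a1 or MISSING, a2 or MISSING))
        ids.append(ind_id.strip())
        blocks.append(pop_idx)
        rows.append(genos)
        block_count += 1
    if pop_idx > 0 and block_count == 0:
        raise GenotypeParseError("empty population block", len(lines))
    if pop_names is not None:
        labels = {b: pop_names[b - 1] for b in set(blocks)}
    else:
        labels = _infer_block_labels(ids, blocks)
    pops = [labels[b] for b in blocks]
    alleles = (
        np.array(rows, dtype=np.int32)
        if rows
        else np.empty((0, len(locus_names), 2), dtype=np.int32)
    )
    ds = GenotypeDataset(alleles, ids, locus_names, np.array(pops, dtype=object))
    ds.validate()
    return ds


def _infer_block_labels(ids: list[str], blocks: list[int]) -> dict[int, str]:
    """Population labels from shared id prefixes (before the last underscore),
    falling back to pop1, pop2, ... when ambiguous."""
    uniq_blocks = sorted(set(blocks))
    candidates = {}
    for b in uniq_blocks:
        prefixes = {ids[k].rsplit("_", 1)[0] for k in range(len(ids))
                    if blocks[k] == b and "_" in ids[k]}
        n_members = sum(1 for k in range(len(ids)) if blocks[k] == b)
        has_all = all("_" in ids[k] for k in range(len(ids)) if blocks[k] == b)
        candidates[b] = prefixes.pop() if (has_all and n_members and
                                           len(prefixes) == 1) else None
    vals = [v for v in candidates.values() if v is not None]
    if len(vals) == len(uniq_blocks) and len(set(vals)) == len(vals):
        return candidates
    return {b: f"pop{b}" for b in uniq_blocks}


def write_genepop(dataset: GenotypeDataset, path, title: str = "parapop export") -> None:
    """Write a GenePop file with 3-digit allele coding.

    Raises ``ValueError`` if any allele size exceeds 999 (the format's coding
    limit).
    """
    a = dataset.alleles
    if a.size and a.max() > 999:
        raise ValueError(f"allele size {a.max()} exceeds GenePop 3-digit limit (999)")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in dataset.locus_names:
            fh.write(name + "\n")
        for pop in dataset.populations:
            fh.write("POP\n")
            for i in dataset.individuals_of_pop(pop):
                codes = []
                for l in range(dataset.n_loci):
                    a1, a2 = a[i, l]
                    a1 = 0 if a1 == MISSING else int(a1)
                    a2 = 0 if a2 == MISSING else int(a2)
                    codes.append(f"{a1:03d}{a2:03d}")
                fh.write(f"{dataset.individual_ids[i]} ,  " + " ".join(codes) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE two-line format
# ---------------------------------------------------------------------------

def read_structure_table(path) -> GenotypeDataset:
    """Read a STRUCTURE table with two rows per individual.

    Layout: optional header row of locus names, then per row
    ``id  pop_label  allele_at_locus1 ... allele_at_locusL``; the two rows of
    an individual carry its two allele copies.  Missing allele = ``-9``.
    """
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise GenotypeParseError("empty file", 1)
    first = lines[0].split()
    has_header = not _all_intlike(first[2:]) if len(first) > 2 else True
    if has_header:
        locus_names = lines[0].split()
        body = lines[1:]
    else:
        locus_names = [f"L{j + 1}" for j in range(len(first) - 2)]
        body = lines
    if len(body) % 2 != 0:
        raise GenotypeParseError("odd number of genotype rows (need 2 per individual)", len(lines))

    ids, pops, rows = [], [], []
    for k in range(0, len(body), 2):
        r1, r2 = body[k].split(), body[k + 1].split()
        lineno = k + 1 + (1 if has_header else 0)
        if len(r1) != len(locus_names) + 2 or len(r2) != len(locus_names) + 2:
            raise GenotypeParseError(
                f"expected {len(locus_names) + 2} columns", lineno + 1
            )
        if r1[0] != r2[0]:
            raise GenotypeParseError(
                f"row pair has mismatched ids {r1[0]!r} / {r2[0]!r}", lineno + 2
            )
        genos = []
        for c1, c2 in zip(r1[2:], r2[2:]):
            a1, a2 = int(c1), int(c2)
            a1 = MISSING if a1 == -9 else a1
            a2 = MISSING if a2 == -9 else a2
            if (a1 == MISSING) != (a2 == MISSING):
                # no half-calls: drop the surviving copy
                a1 = a2 = MISSING
            genos.append((a1, a2))
        ids.append(r1[0])
        pops.append(r1[1])
        rows.append(genos)
    alleles = (
        np.array(rows, dtype=np.int32)
        if rows
        else np.empty((0, len(locus_names), 2), dtype=np.int32)
    )
    ds = GenotypeDataset(alleles, ids, locus_names, np.array(pops, dtype=object))
    ds.validate()
    return ds


def write_structure_table(dataset: GenotypeDataset, path, header: bool = True) -> None:
    """Write the STRUCTURE two-rows-per-individual table (missing = -9)."""
    with open(path, "w") as fh:
        if header:
            fh.write(" ".join(dataset.locus_names) + "\n")
        for i in range(dataset.n_individuals):
            for c in (0, 1):
                vals = [
                    "-9" if v == MISSING else str(int(v)) for v in dataset.alleles[i, :, c]
                ]
                fh.write(
                    f"{dataset.individual_ids[i]} {dataset.pop_of_individual[i]} "
                    + " ".join(vals)
                    + "\n"
                )


def _all_intlike(tokens) -> bool:
    try:
        for t in tokens:
            int(t)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def read_metadata_csv(path, dataset: GenotypeDataset | None = None) -> pd.DataFrame:
    """Read population metadata (population, species, latitude, longitude, altitude).

    If *dataset* is given, the geography and species assignments are attached
    to it in place; populations present in the dataset but absent from the
    metadata raise ``ValueError`` listing the offending labels.
    """
    meta = pd.read_csv(path)
    required = {"population", "species", "latitude", "longitude", "altitude"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    meta = meta.set_index("population")
    for col in ("latitude", "longitude", "altitude"):
        meta[col] = pd.to_numeric(meta[col]).astype(float)
    if dataset is not None:
        unknown = [p for p in dataset.populations if p not in meta.index]
        if unknown:
            raise ValueError(f"populations absent from metadata: {unknown}")
        dataset.species_of_pop = dict(meta["species"])
        dataset.geography = meta[["latitude", "longitude", "altitude"]].copy()
    return meta
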