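"""Readers and writers for the external formats the pipeline touches.

Genotypes travel as VCF v4.2 plus a Stacks-style two-column population map
(sample TAB population, no header).  Multi-locus three-sequence alignments
("triplets": two ingroup sequences and an outgroup) travel as multi-FASTA
with record ids ``locus|role|pair_config`` (roles ``a``, ``b``, ``out``), or
as concatenated relaxed-PHYLIP blocks with the same names.  Run
configuration is YAML.

Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml

MISSING = -1
"""Sentinel for a missing genotype call in :class:`GenotypeMatrix.calls`."""

PAIR_CONFIGS = ("II", "RR", "RI")
TRIPLET_ROLES = ("a", "b", "out")

_ALLOWED_BASES = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


class Locus(NamedTuple):
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass(eq=False)
class GenotypeMatrix:
    """Samples x biallelic-SNP matrix with population labels.

    ``calls[i, j]`` is the count of alternate alleles {0, 1, 2} for diploid
    sample ``i`` at locus ``j``, or :data:`MISSING`.  ``depth`` is an
    optional matching matrix of per-call read counts.
    """

    sample_ids: list[str]
    pop_labels: list[str]
    loci: list[Locus]
    calls: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        ns, nl = len(self.sample_ids), len(self.loci)
        if self.calls.shape != (ns, nl):
            raise ValueError(
                f"calls shape {self.calls.shape} != (samples, loci) = ({ns}, {nl})"
            )
        if self.depth is not None and self.depth.shape != (ns, nl):
            raise ValueError("depth shape does not match calls")
        if len(self.pop_labels) != ns:
            raise ValueError("every sample needs a population label")
        if any(not p for p in self.pop_labels):
            raise ValueError("population labels must be non-empty")
        ok = (self.calls >= 0) & (self.calls <= 2)
        if not np.all(ok | (self.calls == MISSING)):
            raise ValueError("calls must be 0/1/2 or MISSING")
        keys = [(l.contig, l.pos) for l in self.loci]
        if sorted(keys) != keys:
            raise ValueError("loci must be sorted by (contig, position)")
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate locus coordinates")
        for l in self.loci:
            if l.ref == l.alt or len(l.ref) != 1 or len(l.alt) != 1:
                raise ValueError(f"locus {l.contig}:{l.pos} is not a biallelic SNP")

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero([p == pop for p in self.pop_labels])
        if idx.size == 0:
            raise ValueError(f"population {pop!r} not present")
        return idx

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            pop_labels=list(self.pop_labels),
            loci=[self.loci[j] for j in index],
            calls=self.calls[:, index].copy(),
            depth=None if self.depth is None else self.depth[:, index].copy(),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            pop_labels=[self.pop_labels[i] for i in index],
            loci=list(self.loci),
            calls=self.calls[index].copy(),
            depth=None if self.depth is None else self.depth[index].copy(),
        )


@dataclass
class PopulationMap:
    """Total mapping sample id -> population id."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for s, p in self.mapping.items():
            if not p:
                raise ValueError(f"empty population id for sample {s!r}")

    @classmethod
    def read(cls, path: str | Path) -> "PopulationMap":
        mapping: dict[str, str] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {i}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
        return cls(mapping)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{s}\t{p}\n" for s, p in self.mapping.items())
        )


@dataclass(eq=False)
class TripletAlignment:
    """A three-sequence alignment: ingroup pair plus outgroup.

    ``pair_config`` records which species the two ingroup sequences came
    from: ``II`` (both S. invicta), ``RR`` (both S. richteri) or ``RI``
    (one of each).  'N' is permitted and treated as missing at that site.
    """

    locus_id: str
    seq_a: str
    seq_b: str
    seq_out: str
    pair_config: str
    length: int = 0

    def __post_init__(self) -> None:
        if self.pair_config not in PAIR_CONFIGS:
            raise ValueError(f"pair_config must be one of {PAIR_CONFIGS}")
        lens = {len(self.seq_a), len(self.seq_b), len(self.seq_out)}
        if len(lens) != 1:
            raise FormatError(
                f"locus {self.locus_id}: sequences have unequal lengths {sorted(lens)}"
            )
        self.length = len(self.seq_a)
        if self.length == 0:
            raise FormatError(f"locus {self.locus_id}: empty alignment")
        for name, seq in (("a", self.seq_a), ("b", self.seq_b), ("out", self.seq_out)):
            bad = set(seq.upper()) - _ALLOWED_BASES
            if bad:
                raise FormatError(
                    f"locus {self.locus_id}, sequence {name}: non-ACGTN characters {sorted(bad)}"
                )


@dataclass(eq=False)
class TripletDataset:
    triplets: list[TripletAlignment]
    spacing_ok: bool = True

    def __post_init__(self) -> None:
        ids = [t.locus_id for t in self.triplets]
        if len(set(ids)) != len(ids):
            raise ValueError("locus_ids must be unique")

    def __len__(self) -> int:
        return len(self.triplets)

    def __iter__(self):
        return iter(self.triplets)


@dataclass
class RunConfig:
    """Structured-text run configuration (YAML on disk)."""

    filter: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    seed: int = 0
    output: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


# ---------------------------------------------------------------------------
# genotypes: VCF + popmap
# ---------------------------------------------------------------------------

def read_genotypes(
    vcf_path: str | Path,
    popmap_path: str | Path,
    on_multiallelic: str = "error",
) -> GenotypeMatrix:
    """Read a VCF plus population map into a :class:`GenotypeMatrix`.

    Multi-allelic records are rejected (``on_multiallelic="error"``) or
    dropped (``"drop"``).  Haploid genotypes are rejected: the study design
    genotypes diploid females only.  Genotypes ``./.`` become MISSING.
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("error", "drop"):
        raise ValueError("on_multiallelic must be 'error' or 'drop'")
    popmap = PopulationMap.read(popmap_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing_in_map = [s for s in samples if s not in popmap.mapping]
    if missing_in_map:
        raise FormatError(
            f"samples missing from population map: {missing_in_map}"
        )

    loci: list[Locus] = []
    call_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray | None] = []
    n_rejected = 0
    for v in vcf:
        if len(v.ALT) != 1:
            if on_multiallelic == "error":
                raise FormatError(
                    f"multi-allelic record at {v.CHROM}:{v.POS} "
                    f"({v.REF}->{','.join(v.ALT)}); not a biallelic SNP"
                )
            n_rejected += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise FormatError(
                    f"sample {samples[i]} at {v.CHROM}:{v.POS} is not diploid"
                )
            col[i] = MISSING if (-1 in alleles) else int(sum(alleles))
        loci.append(Locus(v.CHROM, int(v.POS), v.REF, v.ALT[0]))
        call_cols.append(col)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        depth_cols.append(None if dp is None else dp[:, 0].astype(np.int32))
    vcf.close()

    order = sorted(range(len(loci)), key=lambda j: (loci[j].contig, loci[j].pos))
    loci = [loci[j] for j in order]
    calls = (
        np.column_stack([call_cols[j] for j in order])
        if loci
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    have_depth = loci and all(d is not None for d in depth_cols)
    depth = (
        np.column_stack([depth_cols[j] for j in order]) if have_depth else None
    )
    matrix = GenotypeMatrix(
        sample_ids=samples,
        pop_labels=[popmap.mapping[s] for s in samples],
        loci=loci,
        calls=calls,
        depth=depth,
    )
    matrix.n_rejected_records = n_rejected  # type: ignore[attr-defined]
    return matrix


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=fireant-demog
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(
    matrix: GenotypeMatrix, vcf_path: str | Path, popmap_path: str | Path
) -> None:
    """Write matrix as an uncompressed VCF v4.2 plus popmap.

    Round-trips through :func:`read_genotypes` on calls, coordinates,
    depths and labels.
    """
    matrix.validate()
    lines = [_VCF_HEADER]
    for contig in dict.fromkeys(l.contig for l in matrix.loci):
        maxpos = max(l.pos for l in matrix.loci if l.contig == contig)
        lines.append(f"##contig=<ID={contig},length={maxpos + 1000}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.sample_ids)
        + "\n"
    )
    fmt = "GT:DP" if matrix.depth is not None else "GT"
    for j, loc in enumerate(matrix.loci):
        cells = []
        for i in range(matrix.n_samples):
            gt = _GT_CODE[int(matrix.calls[i, j])]
            if matrix.depth is not None:
                gt = f"{gt}:{int(matrix.depth[i, j])}"
            cells.append(gt)
        lines.append(
            f"{loc.contig}\t{loc.pos}\t.\t{loc.ref}\t{loc.alt}\t.\tPASS\t.\t{fmt}\t"
            + "\t".join(cells)
            + "\n"
        )
    Path(vcf_path).write_text("".join(lines))
    PopulationMap(dict(zip(matrix.sample_ids, matrix.pop_labels))).write(popmap_path)


# ---------------------------------------------------------------------------
# triplets: multi-FASTA / PHYLIP
# ---------------------------------------------------------------------------

def _parse_triplet_id(record_id: str, path) -> tuple[str, str, str]:
    parts = record_id.split("|")
    if len(parts) != 3 or parts[1] not in TRIPLET_ROLES:
        raise FormatError(
            f"{path}: record id {record_id!r} is not of the form locus|role|config "
            f"with role in {TRIPLET_ROLES}"
        )
    return parts[0], parts[1], parts[2]


def _assemble_triplets(records, path) -> list[TripletAlignment]:
    by_locus: dict[str, dict[str, str]] = {}
    configs: dict[str, str] = {}
    order: list[str] = []
    for rid, seq in records:
        locus, role, config = _parse_triplet_id(rid, path)
        if locus not in by_locus:
            by_locus[locus] = {}
            configs[locus] = config
            order.append(locus)
        if role in by_locus[locus]:
            raise FormatError(f"{path}: duplicate role {role!r} for locus {locus!r}")
        if configs[locus] != config:
            raise FormatError(f"{path}: conflicting pair_config for locus {locus!r}")
        by_locus[locus][role] = seq.upper()
    triplets = []
    for locus in order:
        seqs = by_locus[locus]
        missing = set(TRIPLET_ROLES) - set(seqs)
        if missing:
            raise FormatError(f"{path}: locus {locus!r} is missing roles {sorted(missing)}")
        triplets.append(
            TripletAlignment(
                locus_id=locus,
                seq_a=seqs["a"],
                seq_b=seqs["b"],
                seq_out=seqs["out"],
                pair_config=configs[locus],
            )
        )
    return triplets


def read_triplets(path: str | Path) -> TripletDataset:
    """Read triplet alignments from multi-FASTA or relaxed-PHYLIP blocks."""
    from Bio import SeqIO

    path = Path(path)
    text = path.read_text()
    first = next((c for c in text if not c.isspace()), "")
    if first == ">":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    else:
        records = list(_parse_phylip_blocks(text, path))
    return TripletDataset(triplets=_assemble_triplets(records, path))


def _parse_phylip_blocks(text: str, path):
    lines = [l for l in text.splitlines() if l.strip()]
    i = 0
    while i < len(lines):
        head = lines[i].split()
        if len(head) != 2 or not head[0].isdigit():
            raise FormatError(f"{path}: malformed PHYLIP block header {lines[i]!r}")
        nseq = int(head[0])
        for k in range(nseq):
            parts = lines[i + 1 + k].split(None, 1)
            if len(parts) != 2:
                raise FormatError(f"{path}: malformed PHYLIP sequence line")
            yield parts[0], parts[1].replace(" ", "")
        i += 1 + nseq


def write_triplets(dataset: TripletDataset, path: str | Path) -> None:
    """Write a TripletDataset as multi-FASTA (ids ``locus|role|config``)."""
    lines = []
    for t in dataset:
        for role, seq in (("a", t.seq_a), ("b", t.seq_b), ("out", t.seq_out)):
            lines.append(f">{t.locus_id}|{role}|{t.pair_config}\n{seq}\n")
    Path(path).write_text("".join(lines))
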