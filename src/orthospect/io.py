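"""Readers and writers for every external representation the tool touches.

Supported formats:

* FASTA protein sets (one file per species) — only identifiers and sequence
  lengths are used downstream.
* 12-column tab-separated similarity hit tables (the de-facto standard
  tabular output of protein search tools: query, subject, % identity,
  alignment length, mismatches, gap opens, q.start, q.end, s.start, s.end,
  E-value, bitscore).
* ABC graphs: one ``nodeA nodeB weight`` edge per line; the weight column is
  interpreted as a bitscore.  Node names of the form ``species|protein`` are
  split into a species label and a protein id; plain names are placed in a
  single pseudo-species.
* The grouped-output table with the ``# Species\\tGenes\\tAlg.-Conn.`` header.

Lines starting with ``#`` are treated as comments in hit tables and ABC files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

from Bio import SeqIO

from .graph import PSEUDO_SPECIES, Graph, NodeKey

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import OrthoGroup

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# protein sets


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    species_id: str
    length: int

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if self.length < 1:
            raise ValueError("protein length must be >= 1")


@dataclass(frozen=True)
class ProteinSet:
    species_id: str
    records: tuple[ProteinRecord, ...]

    @property
    def size(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


class ProteinRegistry:
    """Lengths and database sizes of all proteins across species."""

    def __init__(self, sets: Iterable[ProteinSet] = ()) -> None:
        self._length: dict[NodeKey, int] = {}
        self._size: dict[str, int] = {}
        for ps in sets:
            self.add_set(ps)

    def add_set(self, proteins: ProteinSet) -> None:
        if proteins.species_id in self._size:
            raise ValueError(f"duplicate species {proteins.species_id!r}")
        self._size[proteins.species_id] = proteins.size
        for rec in proteins:
            self._length[(rec.species_id, rec.protein_id)] = rec.length

    def length(self, species_id: str, protein_id: str) -> int:
        try:
            return self._length[(species_id, protein_id)]
        except KeyError:
            raise KeyError(
                f"protein {protein_id!r} of species {species_id!r} "
                "is not in the registry"
            ) from None

    def db_size(self, species_id: str) -> int:
        return self._size[species_id]

    @property
    def species(self) -> list[str]:
        return sorted(self._size)

    def __contains__(self, key: NodeKey) -> bool:
        return key in self._length

    def protein_keys(self) -> list[NodeKey]:
        """All (species, protein) pairs, sorted."""
        return sorted(self._length)


def read_fasta(path: str | Path, species_id: str) -> ProteinSet:
    """Read one species' protein set; length counts residues, ignoring
    whitespace and a terminal ``*`` stop."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split())
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        records.append(ProteinRecord(rec.id, species_id, len(seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA entries found")
    return ProteinSet(species_id, tuple(records))


def write_fasta(proteins: ProteinSet, path: str | Path) -> None:
    """Write a protein set with placeholder residues of the stored lengths."""
    with open(path, "w") as fh:
        for rec in proteins:
            fh.write(f">{rec.protein_id}\n")
            seq = "M" + "A" * (rec.length - 1)
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# similarity hit tables


@dataclass(frozen=True)
class SimilarityHit:
    """One directed alignment hit between two proteins."""

    query_id: str
    subject_id: str
    query_species: str
    subject_species: str
    identity_pct: float
    aln_length: int
    evalue: float
    bitscore: float
    qstart: int = 1
    qend: int = 1
    sstart: int = 1
    send: int = 1

    def __post_init__(self) -> None:
        if self.bitscore <= 0:
            raise ValueError("bitscore must be positive")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct must be in [0, 100]")
        if self.qstart > self.qend or self.sstart > self.send:
            raise ValueError("alignment coordinates must satisfy start <= end")

    @property
    def query_key(self) -> NodeKey:
        return (self.query_species, self.query_id)

    @property
    def subject_key(self) -> NodeKey:
        return (self.subject_species, self.subject_id)


def read_hits_table(
    path: str | Path, query_species: str, subject_species: str
) -> list[SimilarityHit]:
    """Parse a 12-column tab-separated hit table.

    Self-hits are retained at parse time; filtering is a later stage.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"found {len(cols)}"
                )
            try:
                hit = SimilarityHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    query_species=query_species,
                    subject_species=subject_species,
                    identity_pct=float(cols[2]),
                    aln_length=int(cols[3]),
                    qstart=int(cols[6]),
                    qend=int(cols[7]),
                    sstart=int(cols[8]),
                    send=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            hits.append(hit)
    return hits


def write_hits_table(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect (mismatches/gap opens set to 0)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.1f}\t"
                f"{h.aln_length}\t0\t0\t{h.qstart}\t{h.qend}\t{h.sstart}\t"
                f"{h.send}\t{h.evalue:.3g}\t{h.bitscore!r}\n"
            )


# ---------------------------------------------------------------------------
# ABC graphs


def _node_name(key: NodeKey) -> str:
    species, protein = key
    return protein if species == PSEUDO_SPECIES else f"{species}|{protein}"


def _parse_node_name(name: str) -> NodeKey:
    if "|" in name:
        species, protein = name.split("|", 1)
        return (species, protein)
    return (PSEUDO_SPECIES, name)


def read_abc_graph(path: str | Path) -> Graph:
    """Read an undirected graph in ABC format (``nodeA nodeB weight``).

    The weight defaults to 1 and duplicate edges keep the maximum weight;
    self-loops are dropped with a warning.  Node names following the
    ``species|protein`` convention are split into species and protein ids.
    """
    graph = Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise FormatError(
                    f"{path}:{lineno}: expected 'nodeA nodeB [weight]'"
                )
            try:
                weight = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                ) from None
            u = graph.add_node(*_parse_node_name(parts[0]))
            v = graph.add_node(*_parse_node_name(parts[1]))
            graph.add_edge(u, v, weight)
    return graph


def write_abc_graph(
    graph: Graph, path: str | Path, header: Sequence[str] = ()
) -> None:
    """Write a graph in ABC format; ``header`` lines are emitted as comments."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for u, v, w in graph.sorted_edges():
            a = _node_name(graph.node_key(u))
            b = _node_name(graph.node_key(v))
            fh.write(f"{a}\t{b}\t{w!r}\n")


# ---------------------------------------------------------------------------
# grouped output table

GROUPS_HEADER = "# Species\tGenes\tAlg.-Conn."


def write_groups_table(
    groups: "Sequence[OrthoGroup]",
    species_order: Sequence[str],
    path: str | Path,
    header: Sequence[str] = (),
) -> None:
    """Write co-orthologous groups as a TSV table.

    One row per group: number of species covered, number of proteins, the
    normalized connectivity at which the group was accepted, then one column
    per species holding its comma-separated protein ids or ``*`` when absent.
    """
    known = set(species_order)
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write(GROUPS_HEADER + "\t" + "\t".join(species_order) + "\n")
        for grp in groups:
            per_species: dict[str, list[str]] = {}
            for species, protein in sorted(grp.members):
                if species not in known:
                    raise ValueError(
                        f"group member {protein!r} has unknown species "
                        f"{species!r}"
                    )
                per_species.setdefault(species, []).append(protein)
            cells = [
                ",".join(per_species[s]) if s in per_species else "*"
                for s in species_order
            ]
            fh.write(
                f"{grp.species_count}\t{grp.protein_count}\t"
                f"{grp.accepted_connectivity:g}\t" + "\t".join(cells) + "\n"
            )


def read_groups_table(path: str | Path) -> list[set[NodeKey]]:
    """Read a grouped-output table back into member sets (for evaluation)."""
    groups: list[set[NodeKey]] = []
    species_order: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("# Species\t"):
                species_order = line.split("\t")[3:]
                continue
            if line.startswith("#"):
                continue
            if species_order is None:
                raise FormatError(f"{path}:{lineno}: data before header")
            cells = line.split("\t")
            members: set[NodeKey] = set()
            for species, cell in zip(species_order, cells[3:]):
                if cell == "*" or not cell:
                    continue
                members.update((species, pid) for pid in cell.split(","))
            if members:
                groups.append(members)
    if species_order is None:
        raise FormatError(f"{path}: missing group-table header")
    return groups
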