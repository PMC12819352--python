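"""Readers and writers for the text formats the pipeline touches.

MEME-minimal motif files, two-column motif->cluster maps, newick trees
(via dendropy) and BED6 interval exports. All genomic coordinates are
0-based half-open throughout the package; BED is the only interval export.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Sentinel cluster label for motifs absent from the cluster map.
UNCLUSTERED = "unclustered"

_ROW_SUM_TOL = 1e-3  # printed probability rows must sum to 1 within this


class MotifParseError(ValueError):
    """Raised when a motif file or block is malformed; names the motif."""


@dataclass
class MotifMatrix:
    """A position frequency matrix over {A, C, G, T}.

    ``probs`` has one row per motif position; each row sums to 1.
    ``cluster_id`` is the JASPAR-style matrix-cluster label used when
    collapsing overlapping instances downstream (``UNCLUSTERED`` if the
    motif has no cluster assignment).
    """

    motif_id: str
    name: str
    probs: np.ndarray
    cluster_id: str = UNCLUSTERED

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise MotifParseError(
                f"motif {self.motif_id!r}: matrix must be w x 4 with w >= 1, "
                f"got shape {self.probs.shape}"
            )
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise MotifParseError(f"motif {self.motif_id!r}: probabilities outside [0, 1]")
        sums = self.probs.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > _ROW_SUM_TOL)
        if bad.size:
            raise MotifParseError(
                f"motif {self.motif_id!r}: row {bad[0]} sums to {sums[bad[0]]:.6f}, not 1"
            )

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def information_content(self) -> float:
        """Total information content in bits (uniform background)."""
        p = np.clip(self.probs, 1e-300, None)
        return float((self.probs * np.log2(p / 0.25)).sum())


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}) on {self.seq_id}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end


# ---------------------------------------------------------------------------
# MEME-minimal motif format


def parse_meme_motifs(
    source: str | Path,
    cluster_map: Mapping[str, str] | None = None,
) -> list[MotifMatrix]:
    """Parse a MEME-minimal motif text file into :class:`MotifMatrix` objects.

    ``source`` is either the text itself or a path to it. ``cluster_map``
    fills ``cluster_id`` (motifs absent from the map get ``UNCLUSTERED``).
    Malformed matrix blocks raise :class:`MotifParseError` naming the motif.
    """
    text = _read_text(source)
    lines = text.splitlines()
    motifs: list[MotifMatrix] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line.startswith("MOTIF"):
            i += 1
            continue
        parts = line.split()
        if len(parts) < 2:
            raise MotifParseError(f"MOTIF line without an identifier: {line!r}")
        motif_id = parts[1]
        name = parts[2] if len(parts) > 2 else motif_id
        i += 1
        # find the letter-probability header
        while i < n and not lines[i].strip().startswith("letter-probability matrix"):
            if lines[i].strip().startswith("MOTIF"):
                raise MotifParseError(f"motif {motif_id!r}: no letter-probability matrix")
            i += 1
        if i >= n:
            raise MotifParseError(f"motif {motif_id!r}: no letter-probability matrix")
        header = lines[i].strip()
        width = _meme_header_int(header, "w=")
        i += 1
        rows: list[list[float]] = []
        while i < n and len(rows) < (width if width is not None else 10**9):
            row_line = lines[i].strip()
            if not row_line or row_line.startswith(("MOTIF", "URL")):
                break
            try:
                row = [float(x) for x in row_line.split()]
            except ValueError as exc:
                raise MotifParseError(f"motif {motif_id!r}: bad matrix row {row_line!r}") from exc
            if len(row) != 4:
                raise MotifParseError(
                    f"motif {motif_id!r}: matrix row has {len(row)} columns, expected 4"
                )
            rows.append(row)
            i += 1
        if width is not None and len(rows) != width:
            raise MotifParseError(
                f"motif {motif_id!r}: header says w={width} but found {len(rows)} rows"
            )
        if not rows:
            raise MotifParseError(f"motif {motif_id!r}: empty matrix")
        cluster = UNCLUSTERED
        if cluster_map is not None:
            cluster = cluster_map.get(motif_id, UNCLUSTERED)
        motifs.append(MotifMatrix(motif_id, name, np.array(rows), cluster))
    return motifs


def _meme_header_int(header: str, key: str) -> int | None:
    toks = header.replace("=", "= ").split()
    for j, tok in enumerate(toks):
        if tok == key and j + 1 < len(toks):
            return int(toks[j + 1])
    return None


def write_meme_motifs(motifs: Iterable[MotifMatrix]) -> str:
    """Serialize motifs as MEME-minimal text (uniform background header)."""
    out = _io.StringIO()
    out.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    out.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
    for m in motifs:
        out.write(f"MOTIF {m.motif_id} {m.name}\n")
        out.write(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n")
        for row in m.probs:
            out.write(" ".join(f"{x:.17g}" for x in row) + "\n")
        out.write("\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# cluster map


def parse_cluster_map(source: str | Path) -> dict[str, str]:
    """Parse a two-column (motif_id TAB cluster_id) table.

    Duplicate motif ids with conflicting clusters raise ``ValueError``;
    consistent duplicates are tolerated. Lines starting with '#' and the
    optional header line ``motif_id<TAB>cluster_id`` are skipped.
    """
    text = _read_text(source)
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"cluster map line {lineno}: expected two columns, got {line!r}")
        motif_id, cluster_id = parts[0], parts[1]
        if lineno == 1 and (motif_id, cluster_id) == ("motif_id", "cluster_id"):
            continue
        if motif_id in mapping and mapping[motif_id] != cluster_id:
            raise ValueError(
                f"cluster map line {lineno}: motif {motif_id!r} mapped to both "
                f"{mapping[motif_id]!r} and {cluster_id!r}"
            )
        mapping[motif_id] = cluster_id
    return mapping


def n_clusters(mapping: Mapping[str, str]) -> int:
    return len(set(mapping.values()))


# ---------------------------------------------------------------------------
# newick trees (dendropy containers)


def parse_newick(source: str | Path) -> dendropy.Tree:
    """Parse a newick tree into a rooted dendropy Tree.

    Tip labels must be unique; malformed newick raises ``ValueError``.
    """
    text = _read_text(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tip labels are not unique")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path lengths keyed by tip label."""
    depths: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


# ---------------------------------------------------------------------------
# BED6


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: float = 0.0


def write_bed(records: Sequence[BedRecord]) -> str:
    """Serialize intervals as sorted 6-column BED (0-based half-open).

    Sorted by (seq_id, start, end), stable within ties by name; byte
    output is deterministic for a fixed input set.
    """
    ordered = sorted(
        records,
        key=lambda r: (r.interval.seq_id, r.interval.start, r.interval.end, r.name),
    )
    lines = [
        f"{r.interval.seq_id}\t{r.interval.start}\t{r.interval.end}\t"
        f"{r.name}\t{_fmt_score(r.score)}\t{r.interval.strand}"
        for r in ordered
    ]
    return "".join(line + "\n" for line in lines)


def _fmt_score(score: float) -> str:
    return f"{score:g}"


# ---------------------------------------------------------------------------
# FASTA helpers (record id convention: "orthogroup|assembly")


def read_fasta(source: str | Path) -> dict[str, str]:
    """Read a FASTA file (or FASTA text) into an id -> sequence dict."""
    from Bio import SeqIO

    text = _read_text(source)
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(_io.StringIO(text), "fasta")
    }


def write_fasta(seqs: Mapping[str, str], width: int = 70) -> str:
    out = _io.StringIO()
    for name, seq in seqs.items():
        out.write(f">{name}\n")
        for i in range(0, len(seq), width):
            out.write(seq[i : i + width] + "\n")
    return out.getvalue()


def split_region_id(rec_id: str) -> tuple[str, str]:
    """Split an 'orthogroup|assembly' FASTA record id."""
    if "|" not in rec_id:
        raise ValueError(f"record id {rec_id!r} is not of the form 'orthogroup|assembly'")
    og, asm = rec_id.split("|", 1)
    return og, asm


def _read_text(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    if "\n" not in s and len(s) < 255:
        try:
            p = Path(s)
            if p.exists():
                return p.read_text()
        except OSError:
            pass
    return s
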