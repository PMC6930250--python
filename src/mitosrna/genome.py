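"""Reference-genome container and annotation I/O.

The vertebrate mitochondrial genome is a circular molecule; by convention the
reference FASTA carries the heavy strand, and the light strand is its reverse
complement.  Features (tRNA/rRNA/mRNA genes, the D-loop control region and the
light-strand origin of replication) are stored with 0-based half-open
coordinates internally; features spanning the sequence origin are stored
"wrapped", with ``end > len(genome)`` and all positions interpreted modulo the
genome length.  GFF3 (1-based, closed intervals) is converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

FEATURE_TYPES = ("tRNA", "rRNA", "mRNA", "D-loop", "origin")
INTERGENIC = "intergenic"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """A stranded, typed genome feature.

    ``start``/``end`` are 0-based half-open heavy-strand coordinates; for a
    feature wrapping the sequence origin ``end`` exceeds the genome length.
    ``strand`` is ``"heavy"`` or ``"light"``.
    """

    feature_id: str
    feature_type: str
    start: int
    end: int
    strand: str = "heavy"
    name: str = ""

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        if self.strand not in ("heavy", "light"):
            raise ValueError(f"strand must be 'heavy' or 'light', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad feature interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Circular heavy-strand reference sequence plus typed, stranded features."""

    sequence: str
    features: list[Feature] = field(default_factory=list)
    circular: bool = True
    name: str = "chrM"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"genome contains non-ACGT characters: {sorted(bad)}")
        self._by_id = {f.feature_id: f for f in self.features}
        if len(self._by_id) != len(self.features):
            raise ValueError("duplicate feature ids")
        self._membership: list[tuple[str, ...]] | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, feature_id: str) -> Feature:
        try:
            return self._by_id[feature_id]
        except KeyError:
            raise KeyError(f"unknown feature id {feature_id!r}") from None

    def fetch(self, start: int, end: int) -> str:
        """Heavy-strand subsequence on [start, end), wrapping the origin."""
        L = len(self)
        if end <= L:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError("interval beyond a linear genome")
        return self.sequence[start:] + self.sequence[: end - L]

    def feature_seq(self, feature: Feature | str) -> str:
        """Feature sequence in its own 5'->3' orientation."""
        if isinstance(feature, str):
            feature = self.feature(feature)
        s = self.fetch(feature.start, feature.end)
        return revcomp(s) if feature.strand == "light" else s

    def membership(self) -> list[tuple[str, ...]]:
        """Per-base tuple of overlapping feature ids (cached)."""
        if self._membership is None:
            L = len(self)
            mem: list[list[str]] = [[] for _ in range(L)]
            for f in self.features:
                for p in range(f.start, f.end):
                    mem[p % L].append(f.feature_id)
            self._membership = [tuple(m) for m in mem]
        return self._membership

    def feature_type_fractions(self) -> dict[str, float]:
        """Fraction of the genome covered by >=1 feature of each type.

        Includes an ``intergenic`` entry for bases covered by no feature.
        """
        L = len(self)
        covered: dict[str, set[int]] = {t: set() for t in FEATURE_TYPES}
        any_cov: set[int] = set()
        for f in self.features:
            pos = {p % L for p in range(f.start, f.end)}
            covered[f.feature_type] |= pos
            any_cov |= pos
        frac = {t: len(pos) / L for t, pos in covered.items()}
        frac[INTERGENIC] = (L - len(any_cov)) / L
        return frac


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O

def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "frame", "attributes"]


def write_gff3(genome: GenomeAnnotation, path: str | Path) -> None:
    rows = []
    for f in genome.features:
        attrs = f"ID={f.feature_id}"
        if f.name:
            attrs += f";Name={f.name}"
        rows.append(
            [genome.name, "mitosrna", f.feature_type, f.start + 1, f.end, ".",
             "+" if f.strand == "heavy" else "-", ".", attrs]
        )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {len(genome)}\n")
        pd.DataFrame(rows, columns=_GFF_COLS).to_csv(fh, sep="\t", header=False, index=False)


def _parse_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[Feature]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_GFF_COLS)
    feats = []
    for i, row in df.iterrows():
        attrs = _parse_attrs(str(row["attributes"]))
        feats.append(
            Feature(
                feature_id=attrs.get("ID", f"feature_{i}"),
                feature_type=str(row["type"]),
                start=int(row["start"]) - 1,
                end=int(row["end"]),
                strand="light" if str(row["strand"]) == "-" else "heavy",
                name=attrs.get("Name", ""),
            )
        )
    return feats


def read_genome(fasta_path: str | Path, gff_path: str | Path,
                name: str = "chrM") -> tuple[GenomeAnnotation, dict[str, str]]:
    """Load the mitochondrial record plus any extra (decoy/nuclear) contigs.

    Returns ``(genome, decoys)`` where ``decoys`` maps contig name -> sequence
    for every FASTA record other than ``name``.
    """
    recs = read_fasta(fasta_path)
    if name not in recs:
        raise ValueError(f"record {name!r} not found in {fasta_path}")
    genome = GenomeAnnotation(sequence=recs[name], features=read_gff3(gff_path), name=name)
    decoys = {k: v for k, v in recs.items() if k != name}
    return genome, decoys
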