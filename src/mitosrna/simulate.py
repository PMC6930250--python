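"""Synthetic small-RNA-seq study generator.

Emulates the study design this package targets: a toy circular mitochondrial
genome carrying the usual feature classes (tRNA / rRNA / mRNA genes, D-loop,
origin of replication), small-RNA libraries for an ordered developmental-stage
x anoxia-treatment design (t0 = time zero, EA = early anoxia, LA = long
anoxia, ER = early recovery, LR = late recovery), and planted, anoxia-
responsive tRNA fragments with known per-condition means, negative-binomial
dispersion and log2 fold changes.  The ground-truth table makes every
downstream recovery property (differential-expression calls, 5'/3' end
classes, conserved cores) decidable without re-reading the reads.

Counts are negative binomial with mean ``mu`` and dispersion ``alpha``
(variance ``mu + alpha * mu**2``); ``alpha = 0`` degrades to Poisson, and an
"exact mean" mode bypasses sampling entirely for deterministic debugging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Feature, GenomeAnnotation, revcomp, write_fasta, write_gff3

STAGES = ("D2", "WS36", "WS40", "WS42")
TREATMENTS = ("t0", "EA", "LA", "ER", "LR")

#: first 12 nt of the Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGG"

_TRNA_NAMES = ("tRNA-cys", "tRNA-ser", "tRNA-leu", "tRNA-phe", "tRNA-gly",
               "tRNA-his", "tRNA-met", "tRNA-trp")


class PlacementError(ValueError):
    """Raised when the requested features cannot fit on the genome."""


@dataclass(frozen=True)
class FeatureSpec:
    """How many features of one class to place, and how long they may be."""

    feature_type: str
    count: int
    length_range: tuple[int, int]
    light_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValueError("bad length range")
        if self.feature_type == "tRNA" and lo < 30:
            raise ValueError("toy tRNA features must be >= 30 nt")


def default_feature_specs() -> list[FeatureSpec]:
    """A vertebrate-mitochondrion-flavoured toy layout (fits in 2 kb)."""
    return [
        FeatureSpec("tRNA", 5, (60, 75), light_fraction=0.3),
        FeatureSpec("rRNA", 2, (120, 180)),
        FeatureSpec("mRNA", 3, (150, 250), light_fraction=0.2),
        FeatureSpec("D-loop", 1, (120, 160)),
        FeatureSpec("origin", 1, (30, 40)),
    ]


@dataclass(frozen=True)
class PlantedFragment:
    """A fragment group planted on one parent feature.

    ``log2fc`` maps ``(stage, treatment)`` to the true log2 fold change of
    that condition relative to the stage's t0 baseline (missing pairs mean
    no change); per-condition expected normalized counts follow as
    ``base_mean * 2**log2fc``.
    """

    fragment_id: str
    parent_feature_id: str
    end_class: str  # five_prime | three_prime | internal
    base_mean: float
    core_length: int = 17
    end_jitter: int = 2
    dispersion: float = 0.1
    log2fc: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end_class not in ("five_prime", "three_prime", "internal"):
            raise ValueError(f"bad end_class {self.end_class!r}")
        if self.base_mean < 0 or self.dispersion < 0:
            raise ValueError("means and dispersion must be >= 0")

    def condition_mean(self, stage: str, treatment: str) -> float:
        return self.base_mean * 2.0 ** self.log2fc.get((stage, treatment), 0.0)


@dataclass(frozen=True)
class SimDesign:
    """The stage x treatment x replicate layout and library-level knobs."""

    stages: tuple[str, ...] = STAGES
    treatments: tuple[str, ...] = TREATMENTS
    replicates: int = 3
    adapter: str = DEFAULT_ADAPTER
    background_reads: int = 300
    read_length: int = 34
    decoy_length: int = 5000
    exact_mean: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if tuple(self.treatments) != TREATMENTS:
            raise ValueError(f"treatments must be exactly {TREATMENTS}")

    def libraries(self) -> list[tuple[str, str, str, int]]:
        """Ordered (library_id, stage, treatment, replicate) tuples."""
        out = []
        for st in self.stages:
            for tr in self.treatments:
                for r in range(1, self.replicates + 1):
                    out.append((f"{st}_{tr}_rep{r}", st, tr, r))
        return out


# ---------------------------------------------------------------------------
# sampling

def nb_sample(rng: np.random.Generator, mean, alpha: float,
              size=None, exact: bool = False) -> np.ndarray:
    """Draw counts with mean ``mean`` and variance ``mean + alpha*mean**2``.

    ``alpha = 0`` is Poisson; ``exact=True`` returns the rounded mean.
    """
    mean = np.asarray(mean, dtype=float)
    if exact:
        out = np.round(mean if size is None else np.broadcast_to(mean, size))
        return out.astype(int)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(mean > 0, n / (n + mean), 1.0)
    return rng.negative_binomial(n, p, size=size)


# ---------------------------------------------------------------------------
# genome construction

def make_toy_genome(seed: int, length: int = 2000,
                    specs: list[FeatureSpec] | None = None) -> GenomeAnnotation:
    """Random circular heavy-strand genome with non-overlapping features.

    Features are laid out in spec order with random intergenic gaps drawn so
    that at least one gap is non-empty.  Deterministic for a given seed.
    """
    if specs is None:
        specs = default_feature_specs()
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))

    lengths, types, lights, names = [], [], [], []
    counters: dict[str, int] = {}
    for spec in specs:
        for _ in range(spec.count):
            counters[spec.feature_type] = counters.get(spec.feature_type, 0) + 1
            i = counters[spec.feature_type]
            lo, hi = spec.length_range
            lengths.append(int(rng.integers(lo, hi + 1)))
            types.append(spec.feature_type)
            lights.append(bool(rng.random() < spec.light_fraction))
            if spec.feature_type == "tRNA":
                names.append(_TRNA_NAMES[(i - 1) % len(_TRNA_NAMES)])
            else:
                names.append(f"{spec.feature_type}-{i}")

    total = sum(lengths)
    n_feat = len(lengths)
    slack = length - total
    if slack < 1:
        raise PlacementError(
            f"features need {total} nt but genome is {length} nt; "
            "no room for an intergenic gap")
    # distribute the slack over n_feat+1 gaps (last gap closes the circle)
    gaps = rng.multinomial(slack, np.full(n_feat + 1, 1.0 / (n_feat + 1)))
    if gaps.max() == 0:  # degenerate; cannot happen with slack >= 1
        gaps[0] = slack

    features = []
    pos = int(gaps[0])
    for k in range(n_feat):
        start = pos
        end = start + lengths[k]
        ftype = types[k]
        fid = f"{ftype.lower().replace('-', '')}_{sum(1 for t in types[:k] if t == ftype) + 1}"
        features.append(Feature(fid, ftype, start, end,
                                strand="light" if lights[k] else "heavy",
                                name=names[k]))
        pos = end + int(gaps[k + 1])
    return GenomeAnnotation(sequence=seq, features=features)


# ---------------------------------------------------------------------------
# fragment planting

def _variant_windows(feat_len: int, frag: PlantedFragment,
                     rng: np.random.Generator) -> list[tuple[int, int]]:
    """(start, end) windows within the oriented feature, all containing the core."""
    n_var = min(frag.end_jitter + 1, 5)
    core = frag.core_length
    if core + frag.end_jitter > feat_len:
        raise ValueError(
            f"core {core} + jitter {frag.end_jitter} exceeds feature length {feat_len}")
    wins = []
    if frag.end_class == "three_prime":
        # anchored at the feature 3' end; 5' end jitters upstream of the core
        for j in range(n_var):
            wins.append((feat_len - core - j, feat_len))
    elif frag.end_class == "five_prime":
        for j in range(n_var):
            wins.append((0, core + j))
    else:
        lo = int(rng.integers(1 + frag.end_jitter, feat_len - core - frag.end_jitter))
        for j in range(n_var):
            side = j % 2  # alternate extension side
            if side == 0:
                wins.append((lo - j // 2, lo + core))
            else:
                wins.append((lo, lo + core + (j + 1) // 2))
    return wins


def plant_fragments(genome: GenomeAnnotation, fragments: list[PlantedFragment],
                    seed: int, stages: tuple[str, ...] = STAGES,
                    treatments: tuple[str, ...] = TREATMENTS) -> pd.DataFrame:
    """Expand fragment groups into sequence variants with expected counts.

    Returns the ground-truth table: one row per variant with its sequence,
    end class, planted core, dispersion, per-(stage, treatment) expected
    normalized count columns ``mean_<stage>_<treatment>`` and true log2 fold
    change columns ``lfc_<stage>_<treatment>`` (relative to the stage's t0).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for frag in fragments:
        feat = genome.feature(frag.parent_feature_id)  # KeyError on unknown id
        fseq = genome.feature_seq(feat)
        wins = _variant_windows(len(feat), frag, rng)
        if frag.end_class == "three_prime":
            core = fseq[len(feat) - frag.core_length:]
        elif frag.end_class == "five_prime":
            core = fseq[: frag.core_length]
        else:
            core = fseq[wins[0][0]: wins[0][0] + frag.core_length]
        for v, (ws, we) in enumerate(wins, start=1):
            seq = fseq[ws:we]
            if not 15 <= len(seq) <= 27:
                raise ValueError(
                    f"variant length {len(seq)} outside the 15-27 nt window")
            row = {
                "variant_id": f"{frag.fragment_id}_v{v}",
                "group_id": frag.fragment_id,
                "parent_feature_id": frag.parent_feature_id,
                "end_class": frag.end_class,
                "sequence": seq,
                "length": len(seq),
                "core": core,
                "dispersion": frag.dispersion,
            }
            for st in stages:
                for tr in treatments:
                    row[f"mean_{st}_{tr}"] = frag.condition_mean(st, tr)
                    row[f"lfc_{st}_{tr}"] = frag.log2fc.get((st, tr), 0.0)
            rows.append(row)
    truth = pd.DataFrame(rows)
    if len(truth) and truth["sequence"].duplicated().any():
        dup = truth.loc[truth["sequence"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"planted variants collide in sequence space: {dup}")
    return truth


def default_fragments(genome: GenomeAnnotation) -> list[PlantedFragment]:
    """The default planted set: anoxia-induced 3' tRNA fragments plus controls.

    Induced groups carry |log2FC| = 4 at long anoxia (and one at early
    recovery) in the two anoxia-tolerant developing stages, with NB
    dispersion 0.1 and baseline mean 200 normalized counts; two null groups
    provide false-positive bait.
    """
    trnas = [f for f in genome.features if f.feature_type == "tRNA"]
    rrnas = [f for f in genome.features if f.feature_type == "rRNA"]
    mrnas = [f for f in genome.features if f.feature_type == "mRNA"]
    up = {("WS36", "LA"): 4.0, ("WS40", "LA"): 4.0}
    frags = [
        PlantedFragment("frag_cys3p", trnas[0].feature_id, "three_prime",
                        base_mean=200.0, log2fc=dict(up)),
        PlantedFragment("frag_ser3p", trnas[1].feature_id, "three_prime",
                        base_mean=200.0, log2fc={("WS36", "LA"): 4.0}),
        PlantedFragment("frag_leu3p", trnas[2].feature_id, "three_prime",
                        base_mean=200.0,
                        log2fc={("WS36", "ER"): 4.0, ("WS36", "LR"): 4.0}),
        PlantedFragment("frag_phe5p", trnas[3].feature_id, "five_prime",
                        base_mean=200.0, log2fc={("WS36", "ER"): 4.0}),
        PlantedFragment("frag_rrna_int", rrnas[0].feature_id, "internal",
                        base_mean=200.0, log2fc={("WS36", "LA"): -4.0}),
        PlantedFragment("frag_null_trna", trnas[4].feature_id, "three_prime",
                        base_mean=100.0),
        PlantedFragment("frag_null_mrna", mrnas[0].feature_id, "internal",
                        base_mean=100.0),
    ]
    return frags


# ---------------------------------------------------------------------------
# library simulation

def _make_read(insert: str, adapter: str, read_length: int) -> str:
    return (insert + adapter)[:read_length]


def simulate_libraries(genome: GenomeAnnotation, truth: pd.DataFrame,
                       design: SimDesign, outdir: str | Path) -> dict[str, Path]:
    """Write FASTQ libraries, reference FASTA/GFF3, sample sheet and truth.

    Each library holds NB-sampled copies of every planted variant plus
    ``background_reads`` uniform 15-27 nt draws from a random decoy contig
    (exercising the genome-alignment retention step downstream).  Every read
    is the insert with the 3' adapter appended, truncated to the fixed read
    length, with constant Phred-33 quality.  Byte-identical for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed)
    decoy = "".join(rng.choice(list("ACGT"), size=design.decoy_length))

    fastq_paths: dict[str, Path] = {}
    sheet_rows = []
    for lib_id, stage, treatment, rep in design.libraries():
        reads: list[str] = []
        for _, var in truth.iterrows():
            mu = float(var[f"mean_{stage}_{treatment}"])
            k = int(nb_sample(rng, mu, float(var["dispersion"]),
                              exact=design.exact_mean))
            reads.extend([var["sequence"]] * k)
        for _ in range(design.background_reads):
            ln = int(rng.integers(15, 28))
            pos = int(rng.integers(0, design.decoy_length - ln))
            ins = decoy[pos: pos + ln]
            if rng.random() < 0.5:
                ins = revcomp(ins)
            reads.append(ins)
        path = outdir / f"{lib_id}.fastq"
        with open(path, "w") as fh:
            for i, ins in enumerate(reads):
                read = _make_read(ins, design.adapter, design.read_length)
                fh.write(f"@{lib_id}_{i}\n{read}\n+\n{'I' * len(read)}\n")
        fastq_paths[lib_id] = path
        sheet_rows.append({"library": lib_id, "stage": stage,
                           "treatment": treatment, "replicate": rep,
                           "fastq": path.name})

    write_fasta(outdir / "genome.fasta", {genome.name: genome.sequence, "decoy": decoy})
    write_gff3(genome, outdir / "annotation.gff3")
    pd.DataFrame(sheet_rows).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return {
        "genome": outdir / "genome.fasta",
        "annotation": outdir / "annotation.gff3",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        **{f"fastq:{k}": v for k, v in fastq_paths.items()},
    }


# ---------------------------------------------------------------------------
# count-level simulation (for DE calibration studies)

def simulate_stage_counts(rng: np.random.Generator, n_null: int, n_de: int,
                          mean: float = 200.0, alpha: float = 0.1,
                          lfc: float = 4.0, de_treatment: str = "LA",
                          treatments: tuple[str, ...] = TREATMENTS,
                          replicates: int = 3) -> tuple[pd.DataFrame, pd.Series]:
    """One stage's count matrix with planted fold changes, plus a truth flag.

    DE rows alternate between +lfc and -lfc at ``de_treatment`` relative to
    t0; null rows are flat at ``mean``.  Columns are ``<treatment>_<rep>``.
    Returns ``(counts, is_de)``.
    """
    cols = [f"{tr}_{r}" for tr in treatments for r in range(1, replicates + 1)]
    n = n_null + n_de
    mu = np.full((n, len(cols)), mean)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    for j, c in enumerate(cols):
        if c.rsplit("_", 1)[0] == de_treatment:
            mu[:n_de, j] = mean * 2.0 ** (signs * lfc)
    counts = nb_sample(rng, mu, alpha)
    idx = [f"seq_{i}" for i in range(n)]
    is_de = pd.Series([i < n_de for i in range(n)], index=idx)
    return pd.DataFrame(counts, index=idx, columns=cols), is_de
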