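"""Exact alignment of small RNAs to the circular mitochondrial genome and
strand / feature / overlap cataloging.

A sequence is a mitosRNA iff it aligns with 100% identity somewhere on the
mitochondrial genome, on either strand; circularity is honoured by also
searching windows that wrap the sequence origin.  A hit is classified as
``single_feature`` when it lies entirely within one annotated feature,
``overlapping_features`` when it touches two or more features or extends
beyond a feature into intergenic sequence, and ``intergenic`` when it
touches no feature at all.  Summaries mirror the field's usual strand x
overlap-class catalog tables, with feature-type columns counting each
overlapped type once per sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FEATURE_TYPES, INTERGENIC, GenomeAnnotation, revcomp

log = logging.getLogger(__name__)

OVERLAP_CLASSES = ("single_feature", "overlapping_features", "intergenic")
STRANDS = ("heavy", "light")


@dataclass(frozen=True)
class AlignmentHit:
    """One perfect-match placement on the genome.

    Coordinates are 0-based half-open on the heavy strand; for a hit that
    wraps the origin, ``end`` exceeds the genome length and positions are
    interpreted modulo the length.  A light-strand hit means the read equals
    the reverse complement of the heavy-strand interval.
    """

    start: int
    end: int
    strand: str
    wraps_origin: bool = False


@dataclass(frozen=True)
class MitosAnnotation:
    """A hit plus its feature-overlap classification.

    ``features`` lists overlapped feature ids in read order (with
    ``"intergenic"`` marking uncovered stretches); the extensions count hit
    bases outside the first/last feature at the read's 5'/3' end.
    """

    hit: AlignmentHit
    overlap_class: str
    features: tuple[str, ...]
    feature_types: tuple[str, ...]
    upstream_extension: int = 0
    downstream_extension: int = 0


def exact_align(seq: str, genome: GenomeAnnotation) -> list[AlignmentHit]:
    """All perfect-match placements of ``seq`` on both strands.

    Searches the doubled sequence when the genome is circular so hits
    spanning the origin are found once, reported with ``end > len(genome)``.
    Hits are ordered by start with heavy before light on ties.
    """
    L = len(genome)
    m = len(seq)
    if m > L:
        return []
    hay = genome.sequence + (genome.sequence[: m - 1] if genome.circular else "")
    hits = []
    for strand, query in (("heavy", seq), ("light", revcomp(seq))):
        i = hay.find(query)
        while i != -1:
            hits.append(AlignmentHit(start=i, end=i + m, strand=strand,
                                     wraps_origin=i + m > L))
            i = hay.find(query, i + 1)
    hits.sort(key=lambda h: (h.start, h.strand != "heavy"))
    return hits


def annotate_hit(hit: AlignmentHit, genome: GenomeAnnotation) -> MitosAnnotation:
    """Classify a hit by the features its bases touch.

    Membership is evaluated per base (mod genome length); features are
    reported in the order first encountered along the read's own 5'->3'
    direction, with ``intergenic`` entries for uncovered stretches.  A hit
    entirely inside one feature is ``single_feature``; any intergenic base or
    second feature makes it ``overlapping_features`` (zero-extension
    allowance), and a hit touching no feature is ``intergenic``.
    """
    L = len(genome)
    mem = genome.membership()
    positions = [(hit.start + i) % L for i in range(hit.end - hit.start)]
    if hit.strand == "light":  # read 5'->3' runs right-to-left on the heavy strand
        positions = positions[::-1]

    per_base: list[tuple[str, ...]] = [mem[p] for p in positions]
    feat_order: list[str] = []
    for fb in per_base:
        for label in (fb or (INTERGENIC,)):
            if label not in feat_order:
                feat_order.append(label)

    n = len(positions)
    up = 0
    while up < n and not per_base[up]:
        up += 1
    down = 0
    while down < n - up and not per_base[n - 1 - down]:
        down += 1

    real = [f for f in feat_order if f != INTERGENIC]
    if not real:
        klass = "intergenic"
    elif len(real) == 1 and INTERGENIC not in feat_order:
        klass = "single_feature"
    else:
        klass = "overlapping_features"

    types = []
    for f in feat_order:
        t = INTERGENIC if f == INTERGENIC else genome.feature(f).feature_type
        if t not in types:
            types.append(t)
    return MitosAnnotation(hit=hit, overlap_class=klass,
                           features=tuple(feat_order), feature_types=tuple(types),
                           upstream_extension=up, downstream_extension=down)


@dataclass
class Catalog:
    """Per-sequence primary annotation plus alignment flags.

    ``table`` has one row per mitosRNA (index = sequence) with the primary
    hit's coordinates and classification; ``flags`` labels every input
    sequence as ``mito`` / ``decoy`` / ``unaligned``; ``all_hits`` keeps
    every placement of multi-mapping sequences.
    """

    table: pd.DataFrame
    flags: pd.Series
    all_hits: dict[str, list[MitosAnnotation]] = field(default_factory=dict)

    @property
    def mito_sequences(self) -> pd.Index:
        return self.table.index


def _aligns_to_decoy(seq: str, decoys: dict[str, str]) -> bool:
    rc = revcomp(seq)
    return any(seq in d or rc in d for d in decoys.values())


def build_catalog(sequences, genome: GenomeAnnotation,
                  decoys: dict[str, str] | None = None) -> Catalog:
    """Align every sequence and annotate the mitochondrial ones.

    Multi-mapping sequences carry all annotations in ``all_hits`` but appear
    once in ``table`` via the primary hit (lowest heavy-strand start, heavy
    preferred over light on ties).  Sequences matching only a decoy contig
    are flagged ``decoy``; sequences matching nothing are ``unaligned``.
    """
    decoys = decoys or {}
    rows, flags, all_hits = [], {}, {}
    for seq in sequences:
        hits = exact_align(seq, genome)
        if hits:
            anns = [annotate_hit(h, genome) for h in hits]
            all_hits[seq] = anns
            a = anns[0]  # exact_align returns primary-ordered hits
            rows.append({
                "sequence": seq,
                "start": a.hit.start,
                "end": a.hit.end,
                "strand": a.hit.strand,
                "wraps_origin": a.hit.wraps_origin,
                "overlap_class": a.overlap_class,
                "features": ",".join(a.features),
                "feature_types": list(a.feature_types),
                "upstream_extension": a.upstream_extension,
                "downstream_extension": a.downstream_extension,
                "n_hits": len(hits),
            })
            flags[seq] = "mito"
        elif _aligns_to_decoy(seq, decoys):
            flags[seq] = "decoy"
        else:
            flags[seq] = "unaligned"
    table = pd.DataFrame(rows).set_index("sequence") if rows else pd.DataFrame(
        columns=["start", "end", "strand", "wraps_origin", "overlap_class",
                 "features", "feature_types", "upstream_extension",
                 "downstream_extension", "n_hits"])
    return Catalog(table=table, flags=pd.Series(flags, name="flag", dtype=object),
                   all_hits=all_hits)


@dataclass
class CatalogSummary:
    """Strand x overlap-class counts with feature-type columns.

    ``table`` rows are (overlap_class, strand); columns are ``count``,
    ``percent`` (of ``total``, one decimal) and one column per feature type
    plus ``intergenic``.  ``empty`` flags a zero-size subset, in which case
    percentages are reported as 0.0.
    """

    table: pd.DataFrame
    total: int
    empty: bool = False


def summarize_catalog(catalog: Catalog | pd.DataFrame,
                      subset=None) -> CatalogSummary:
    """Tabulate a catalog (or a subset of its sequences).

    Feature-type columns count, for single-feature rows, the one feature's
    type; for overlapping rows, every overlapped type once (so type columns
    in overlapping rows may sum to more than the row count).
    """
    df = catalog.table if isinstance(catalog, Catalog) else catalog
    if subset is not None:
        df = df.loc[df.index.intersection(pd.Index(subset))]
    total = len(df)
    idx = pd.MultiIndex.from_product(
        [("single_feature", "overlapping_features"), STRANDS],
        names=["overlap_class", "strand"])
    cols = ["count", "percent", *FEATURE_TYPES, INTERGENIC]
    out = pd.DataFrame(0.0, index=idx, columns=cols)
    for (klass, strand) in idx:
        sub = df[(df["overlap_class"] == klass) & (df["strand"] == strand)]
        out.loc[(klass, strand), "count"] = len(sub)
        for types in sub["feature_types"]:
            for t in types:
                out.loc[(klass, strand), t] += 1
    if total:
        out["percent"] = (out["count"] / total * 100).round(1)
    else:
        out["percent"] = 0.0
    counts = out["count"].astype(int)
    out["count"] = counts
    for c in (*FEATURE_TYPES, INTERGENIC):
        out[c] = out[c].astype(int)
    return CatalogSummary(table=out, total=total, empty=total == 0)


def feature_enrichment(catalog: Catalog | pd.DataFrame,
                       genome: GenomeAnnotation) -> pd.DataFrame:
    """Observed vs genome-composition fractions per feature type.

    For each type, the observed count is the number of cataloged sequences
    overlapping >=1 feature of that type; the expected fraction is the
    proportion of genome bases covered by that type.  A two-sided exact
    binomial test is applied per type with Benjamini-Hochberg correction
    across types.
    """
    from .de import bh_adjust

    df = catalog.table if isinstance(catalog, Catalog) else catalog
    n = len(df)
    if n == 0:
        raise ValueError("cannot compute enrichment on an empty catalog")
    genome_frac = genome.feature_type_fractions()
    rows = []
    for t in (*FEATURE_TYPES, INTERGENIC):
        obs = int(sum(t in types for types in df["feature_types"]))
        p0 = genome_frac[t]
        if 0 < p0 < 1:
            pval = stats.binomtest(obs, n, p0, alternative="two-sided").pvalue
        else:
            pval = 1.0 if (p0 == 0) == (obs == 0) else 0.0
        obs_frac = obs / n
        rows.append({"feature_type": t, "observed": obs,
                     "observed_fraction": obs_frac, "genome_fraction": p0,
                     "ratio": obs_frac / p0 if p0 > 0 else np.inf,
                     "pvalue": pval})
    res = pd.DataFrame(rows).set_index("feature_type")
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res
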