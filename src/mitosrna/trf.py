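"""tRNA-fragment (tRF) analytics.

Per-base coverage profiles over a feature window, 5'/3' end classification of
fragments relative to their parent feature (in the feature's own 5'->3'
orientation, so light-strand features are handled by coordinate flipping),
k-means clustering of expression patterns, conserved-core discovery for
antisense probe design, and the mitosRNA expression fraction with its
correlation against stage-level physiological traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .catalog import Catalog
from .genome import Feature, GenomeAnnotation, revcomp

log = logging.getLogger(__name__)

END_CLASSES = ("five_prime", "three_prime", "internal", "full_length")


# ---------------------------------------------------------------------------
# coverage

def coverage_profile(catalog: Catalog, norm_counts: pd.DataFrame,
                     genome: GenomeAnnotation, feature_id: str,
                     samples: list[str], flank: int = 5) -> pd.Series:
    """Sum of normalized read counts covering each base of a feature window.

    Positions run 5'->3' along the feature from ``-flank`` to
    ``len(feature) + flank - 1`` (flanks make upstream/downstream extensions
    visible).  Each cataloged read contributes its total normalized count in
    ``samples`` to every window base it covers; an empty sample list yields
    an all-zero profile.
    """
    feat = genome.feature(feature_id)
    L = len(genome)
    flen = len(feat)
    # window in heavy-strand coordinates, then oriented
    win_start, win_end = feat.start - flank, feat.end + flank
    win_pos = [p % L for p in range(win_start, win_end)]
    if feat.strand == "light":
        win_pos = win_pos[::-1]
    pos_to_idx = {p: i for i, p in enumerate(win_pos)}
    values = np.zeros(len(win_pos))

    weights = norm_counts[samples].sum(axis=1) if samples else None
    for seq, row in catalog.table.iterrows():
        if weights is None or seq not in weights.index:
            continue
        w = float(weights.loc[seq])
        if w == 0:
            continue
        for p in range(int(row["start"]), int(row["end"])):
            i = pos_to_idx.get(p % L)
            if i is not None:
                values[i] += w
    index = pd.RangeIndex(-flank, flen + flank, name="position")
    return pd.Series(values, index=index, name=feature_id)


# ---------------------------------------------------------------------------
# end classification

def _oriented_offsets(hit_start: int, hit_end: int, feat: Feature,
                      genome_length: int) -> tuple[int, int]:
    """(d5, d3): signed distances of the hit's 5'/3' ends from the feature's.

    Positive d5 means the hit 5' end lies inside the feature; positive d3
    means the hit 3' end falls short of the feature 3' end.  Computed in the
    feature's own orientation, with wrapped coordinates unwrapped onto the
    feature's frame.
    """
    L = genome_length
    # unwrap hit start to the representative closest to the feature
    hs = hit_start
    best = min((hs + k * L for k in (-1, 0, 1)),
               key=lambda s: abs(s - feat.start))
    hs = best
    he = hs + (hit_end - hit_start)
    if feat.strand == "heavy":
        d5 = hs - feat.start
        d3 = feat.end - he
    else:
        d5 = feat.end - he
        d3 = hs - feat.start
    return d5, d3


def classify_end(hit_start: int, hit_end: int, feat: Feature,
                 genome_length: int, tau: int = 2) -> str:
    """Assign a fragment to the five_prime / three_prime / internal /
    full_length class with end tolerance ``tau`` nt.

    A fragment is five_prime when its 5' end sits within ``tau`` of the
    feature's 5' end while its 3' end does not reach the feature's 3' end
    (symmetrically for three_prime); both ends within tolerance means
    full_length, neither means internal.  Raises if the hit does not overlap
    the feature.
    """
    d5, d3 = _oriented_offsets(hit_start, hit_end, feat, genome_length)
    flen = len(feat)
    hlen = hit_end - hit_start
    # overlap check in the feature frame
    if d5 >= flen or d3 >= flen or d5 + hlen <= 0 or d3 + hlen <= 0:
        raise ValueError("hit does not overlap the feature")
    near5, near3 = abs(d5) <= tau, abs(d3) <= tau
    if near5 and near3:
        return "full_length"
    if near5:
        return "five_prime"
    if near3:
        return "three_prime"
    return "internal"


def classify_catalog_ends(catalog: Catalog, genome: GenomeAnnotation,
                          feature_type: str = "tRNA", tau: int = 2) -> pd.DataFrame:
    """End class of every cataloged sequence against each overlapped feature
    of the given type."""
    rows = []
    for seq, row in catalog.table.iterrows():
        for fid in str(row["features"]).split(","):
            if fid in ("", "intergenic"):
                continue
            feat = genome.feature(fid)
            if feat.feature_type != feature_type:
                continue
            rows.append({
                "sequence": seq, "feature_id": fid, "feature_name": feat.name,
                "end_class": classify_end(int(row["start"]), int(row["end"]),
                                          feat, len(genome), tau=tau),
            })
    return pd.DataFrame(rows, columns=["sequence", "feature_id",
                                       "feature_name", "end_class"])


# ---------------------------------------------------------------------------
# expression clustering

@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series
    centroids: np.ndarray
    wcss: float
    seed: int


def cluster_expression(values: pd.DataFrame, k: int = 3, seed: int = 0,
                       restarts: int = 20) -> ClusterModel:
    """k-means (Lloyd, k-means++ seeding, Euclidean) on expression patterns.

    Missing values are imputed as 0 with a logged note; the best of
    ``restarts`` runs by within-cluster sum of squares is kept, and the
    result is deterministic for a given seed.
    """
    if k > len(values):
        raise ValueError(f"k={k} exceeds the {len(values)} available rows")
    x = values.to_numpy(dtype=float)
    if np.isnan(x).any():
        log.info("imputing %d missing heatmap values as 0", int(np.isnan(x).sum()))
        x = np.nan_to_num(x, nan=0.0)
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                random_state=seed, algorithm="lloyd").fit(x)
    return ClusterModel(k=k,
                        assignments=pd.Series(km.labels_, index=values.index,
                                              name="cluster"),
                        centroids=km.cluster_centers_,
                        wcss=float(km.inertia_), seed=seed)


# ---------------------------------------------------------------------------
# conserved-core probe design

@dataclass(frozen=True)
class ProbeCore:
    """The maximal substring shared by a fragment group, and its probe.

    ``probe`` is the reverse complement of the core — the sequence an
    antisense oligonucleotide must carry to bind every group member.
    ``degenerate`` flags an empty core (no shared substring).
    """

    core: str
    probe: str
    members: tuple[str, ...]

    @property
    def core_length(self) -> int:
        return len(self.core)

    @property
    def degenerate(self) -> bool:
        return not self.core


def find_conserved_core(seqs) -> ProbeCore:
    """Longest substring common to all sequences (ties -> leftmost in the
    first sequence); the probe is its reverse complement.

    Any common substring is a substring of the first sequence, so candidates
    are enumerated from it longest-first, leftmost-first.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("need at least one sequence")
    first, rest = seqs[0], seqs[1:]
    for L in range(len(first), 0, -1):
        for i in range(len(first) - L + 1):
            cand = first[i:i + L]
            if all(cand in s for s in rest):
                return ProbeCore(core=cand, probe=revcomp(cand),
                                 members=tuple(seqs))
    log.warning("no common substring among %d sequences", len(seqs))
    return ProbeCore(core="", probe="", members=tuple(seqs))


# ---------------------------------------------------------------------------
# mitosRNA fraction and trait correlation

def mitos_fraction(norm_counts: pd.DataFrame, mito_flags: pd.Series,
                   samples: list[str]) -> float:
    """Summed normalized mitosRNA expression over all small-RNA expression
    within the given samples."""
    if not samples:
        raise ValueError("sample group is empty")
    total = float(norm_counts[samples].to_numpy().sum())
    if total == 0:
        raise ValueError("zero total expression in the sample group")
    mito = mito_flags.reindex(norm_counts.index).eq("mito")
    return float(norm_counts.loc[mito, samples].to_numpy().sum()) / total


def trait_correlation(fractions: pd.Series, traits: pd.DataFrame,
                      trait: str) -> tuple[float, float]:
    """Pearson correlation of per-stage mitosRNA fractions with a trait.

    ``fractions`` is indexed by stage; ``traits`` is indexed by stage with
    one column per trait.  Returns (r, two-sided p from the t transform with
    n-2 df).  Requires >=3 stages with both values; zero variance yields
    (nan, nan) with a warning.
    """
    joined = pd.concat([fractions.rename("fraction"), traits[trait]],
                       axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >=3 stages with both a fraction and a trait value")
    x, y = joined["fraction"].to_numpy(), joined[trait].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        log.warning("zero variance in %s correlation inputs", trait)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
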