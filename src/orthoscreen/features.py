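"""The ten alignment-level attributes used to classify clusters.

For each cluster MSA we compute: the count of randomly aligned positions
(a Monte-Carlo sliding-window score, see :mod:`orthoscreen.randomness`),
alignment length, number of sequences, total gaps, total amino acids,
the range of ungapped member lengths, and the between-sequence standard
deviation of per-sequence amino-acid composition in each of four
physicochemical classes (charged, uncharged/polar, hydrophobic, special).

The compositional dispersions use each sequence's own ungapped residue
count as the denominator (a length correction) and the Bessel n−1
divisor across sequences (an unbiased variance estimator); 'X' residues
are excluded from class counts, since an unknown residue has no
physicochemical class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .cluster_io import GAP, STANDARD_AA, UNKNOWN_RESIDUE, Alignment, Cluster
from .msa_align import AlignParams, ensure_aligned
from .randomness import RandomnessParams, random_positions

CLASS_NAMES = ("charged", "uncharged", "special", "hydrophobic")


@dataclass(frozen=True)
class AminoClassScheme:
    """Disjoint physicochemical partition of the 20 standard residues."""

    charged: frozenset = frozenset("DEKRH")
    uncharged: frozenset = frozenset("STNQY")
    hydrophobic: frozenset = frozenset("AVLIMFW")
    special: frozenset = frozenset("CGP")

    def __post_init__(self) -> None:
        sets = [self.charged, self.uncharged, self.hydrophobic, self.special]
        union = frozenset().union(*sets)
        if union != frozenset(STANDARD_AA):
            raise ValueError(
                "class scheme must partition the 20 standard residues; "
                f"union misses {sorted(frozenset(STANDARD_AA) - union)} / has "
                f"extra {sorted(union - frozenset(STANDARD_AA))}"
            )
        if sum(len(s) for s in sets) != 20:
            raise ValueError("class sets must be disjoint")

    def residues(self, cls: str) -> frozenset:
        if cls not in CLASS_NAMES:
            raise KeyError(f"unknown class {cls!r}; choose from {CLASS_NAMES}")
        return getattr(self, cls)


DEFAULT_SCHEME = AminoClassScheme()

#: canonical feature order for model schemas and CSV headers
FEATURE_NAMES = (
    "aliscore",
    "length",
    "n_sequences",
    "n_gaps",
    "n_amino_acids",
    "range",
    "sd_charged",
    "sd_uncharged",
    "sd_special",
    "sd_hydrophobic",
)


@dataclass(frozen=True)
class FeatureVector:
    aliscore: int
    length: int
    n_sequences: int
    n_gaps: int
    n_amino_acids: int
    range: int
    sd_charged: float
    sd_uncharged: float
    sd_special: float
    sd_hydrophobic: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in FEATURE_NAMES}


def count_gaps(aln: Alignment) -> int:
    """Total gap characters over the whole alignment matrix."""
    return sum(r.residues.count(GAP) for r in aln.rows)


def count_amino_acids(aln: Alignment) -> int:
    """Total non-gap characters ('X' counts as a residue)."""
    return aln.length * aln.n_rows - count_gaps(aln)


def sequence_range(cluster: Cluster) -> int:
    """Longest minus shortest ungapped member length."""
    lengths = [m.ungapped_length() for m in cluster.members]
    return max(lengths) - min(lengths)


def _class_proportions(
    aln: Alignment, residue_set: frozenset
) -> np.ndarray:
    props = np.empty(aln.n_rows)
    for i, row in enumerate(aln.rows):
        countable = 0
        in_class = 0
        for c in row.residues:
            if c == GAP or c == UNKNOWN_RESIDUE:
                continue
            countable += 1
            if c in residue_set:
                in_class += 1
        if countable == 0:
            raise ValueError(
                f"row {row.id!r} has no countable residues (all gap/X); "
                "cannot form a composition proportion"
            )
        props[i] = in_class / countable
    return props


def class_dispersion(
    aln: Alignment,
    scheme: AminoClassScheme = DEFAULT_SCHEME,
    cls: str = "charged",
    kind: Literal["sd", "variance"] = "sd",
) -> float:
    """Between-sequence dispersion of per-sequence class composition.

    Proportions are per sequence over its own ungapped non-'X' residues;
    the variance uses the n−1 divisor.  ``kind`` toggles standard
    deviation (default, matching the emitted feature) vs raw variance.
    """
    props = _class_proportions(aln, scheme.residues(cls))
    var = float(np.var(props, ddof=1))
    return var if kind == "variance" else float(np.sqrt(var))


def featurize(
    cluster: Cluster,
    scheme: AminoClassScheme = DEFAULT_SCHEME,
    rparams: RandomnessParams | None = None,
    align_params: AlignParams | None = None,
    dispersion: Literal["sd", "variance"] = "sd",
) -> FeatureVector:
    """Compute the full ten-attribute vector for one cluster.

    Aligns the cluster first if no alignment is present.  A precomputed
    randomly-aligned-position count attached to the cluster takes
    precedence over the internal Monte-Carlo scorer.
    """
    rparams = rparams or RandomnessParams()
    cluster = ensure_aligned(cluster, align_params)
    aln = cluster.alignment
    assert aln is not None
    if cluster.aliscore_precomputed is not None:
        aliscore = cluster.aliscore_precomputed
    else:
        aliscore = random_positions(aln, rparams)
    return FeatureVector(
        aliscore=aliscore,
        length=aln.length,
        n_sequences=aln.n_rows,
        n_gaps=count_gaps(aln),
        n_amino_acids=count_amino_acids(aln),
        range=sequence_range(cluster),
        sd_charged=class_dispersion(aln, scheme, "charged", dispersion),
        sd_uncharged=class_dispersion(aln, scheme, "uncharged", dispersion),
        sd_special=class_dispersion(aln, scheme, "special", dispersion),
        sd_hydrophobic=class_dispersion(aln, scheme, "hydrophobic", dispersion),
    )


def feature_table(
    clusters: Iterable[Cluster],
    scheme: AminoClassScheme = DEFAULT_SCHEME,
    rparams: RandomnessParams | None = None,
    align_params: AlignParams | None = None,
    with_labels: bool = True,
) -> pd.DataFrame:
    """One row per cluster: cluster_id, the ten features, optional label."""
    rows = []
    for cluster in clusters:
        rec = {"cluster_id": cluster.cluster_id}
        rec.update(featurize(cluster, scheme, rparams, align_params).as_dict())
        if with_labels:
            rec["label"] = cluster.label.value
            rec["provenance"] = cluster.provenance.value
        rows.append(rec)
    return pd.DataFrame(rows)


def attach_precomputed(cluster: Cluster, aliscore_value: int) -> None:
    """Attach an externally computed randomly-aligned-position count.

    The value (e.g. from an actual ALISCORE run) is used verbatim by
    :func:`featurize` instead of the internal scorer.
    """
    if cluster.alignment is None:
        raise ValueError("attach an alignment before a precomputed score")
    if not (0 <= aliscore_value <= cluster.alignment.length):
        raise ValueError(
            f"precomputed count {aliscore_value} outside [0, "
            f"{cluster.alignment.length}]"
        )
    cluster.aliscore_precomputed = int(aliscore_value)
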