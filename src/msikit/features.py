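"""Per-locus instability statistics and fixed-order feature vectors.

Each microsatellite locus contributes two numbers to a sample's feature
vector:

* ``n_peaks`` — the number of distinct indel allele lengths observed at
  the locus, the sequencing analog of distinct fragment-length peaks in a
  capillary-electrophoresis chromatogram;
* ``mean_indel_length`` — the arithmetic mean of those distinct signed
  length changes (bp; deletions negative).

With an L-locus panel every sample becomes a 2L-dimensional vector in
feature_index order (58 dimensions for the 29-locus panel), which is the
input to the centroid classifier.  A locus with no indel calls contributes
(0, 0.0) so vectors stay fixed-length; ``callable_loci`` counts loci with
at least one call so QC can flag under-covered samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

from .core_io import IndelCall, MsiLocus, ValidationError


@dataclass(frozen=True)
class LocusFeatures:
    """The (n_peaks, mean indel length) pair for one locus."""

    n_peaks: int
    mean_indel_length: float


@dataclass(frozen=True)
class FeatureVector:
    """A sample's fixed-order 2L feature vector."""

    sample_id: str
    values: np.ndarray
    callable_loci: int


@dataclass
class FeatureMatrix:
    """A cohort's feature vectors in a dense n_samples x 2L array."""

    sample_ids: list[str]
    locus_names: list[str]
    values: np.ndarray
    callable_loci: np.ndarray

    def __iter__(self) -> Iterator[FeatureVector]:
        for i, sid in enumerate(self.sample_ids):
            yield FeatureVector(sid, self.values[i], int(self.callable_loci[i]))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def locus_features(calls: Sequence[IndelCall]) -> LocusFeatures:
    """Compute (n_peaks, mean indel length) for one locus.

    Alleles are deduplicated by signed ``length_delta``: n_peaks is the
    number of distinct deltas and the mean is taken over the distinct
    deltas, each weighted once.  An empty call list gives (0, 0.0).
    """
    names = {c.locus_name for c in calls if c.locus_name is not None}
    if len(names) > 1:
        raise ValidationError(f"calls span multiple loci: {sorted(names)}")
    deltas = {c.length_delta for c in calls}
    if 0 in deltas:
        raise ValidationError("length_delta of 0 reached locus_features; upstream filter violated")
    if not deltas:
        return LocusFeatures(0, 0.0)
    return LocusFeatures(len(deltas), float(np.mean(sorted(deltas))))


def build_feature_matrix(
    cohort: Mapping[str, Mapping[str, Sequence[IndelCall]]],
    loci: Sequence[MsiLocus],
) -> FeatureMatrix:
    """Assemble the cohort feature matrix.

    ``cohort`` maps sample_id -> (locus_name -> calls).  Column order is
    [locus0_npeaks, locus0_meanlen, locus1_npeaks, ...] following
    feature_index.  A sample mentioning a locus outside the panel is an
    error; panel loci absent from a sample's map count as empty.
    """
    panel = {l.name for l in loci}
    ordered = sorted(loci, key=lambda l: l.feature_index)
    sample_ids = list(cohort.keys())
    values = np.zeros((len(sample_ids), 2 * len(ordered)))
    callable_loci = np.zeros(len(sample_ids), dtype=int)
    for i, sid in enumerate(sample_ids):
        locus_map = cohort[sid]
        extra = set(locus_map) - panel
        if extra:
            raise ValidationError(
                f"sample {sid!r} has calls at loci outside the panel: {sorted(extra)}"
            )
        for j, locus in enumerate(ordered):
            feats = locus_features(locus_map.get(locus.name, ()))
            values[i, 2 * j] = feats.n_peaks
            values[i, 2 * j + 1] = feats.mean_indel_length
            if feats.n_peaks > 0:
                callable_loci[i] += 1
    return FeatureMatrix(sample_ids, [l.name for l in ordered], values, callable_loci)


def locus_prevalence_filter(
    matrix: FeatureMatrix,
    loci: Sequence[MsiLocus],
    min_fraction: float = 0.8,
) -> list[MsiLocus]:
    """Keep loci that consistently generate peaks across the cohort.

    A locus is retained iff the fraction of samples with n_peaks >= 1 at
    that locus is strictly greater than ``min_fraction`` (the panel's 29
    loci were those informative in > 80% of training cases).  Retained
    loci are re-indexed 0..L'-1 preserving relative order.
    """
    if matrix.n_samples == 0:
        raise ValidationError("prevalence filter needs a nonempty cohort")
    if not (0 < min_fraction <= 1):
        raise ValidationError(f"min_fraction must be in (0, 1], got {min_fraction}")
    ordered = sorted(loci, key=lambda l: l.feature_index)
    if [l.name for l in ordered] != matrix.locus_names:
        raise ValidationError("locus list does not match feature-matrix columns")
    npeaks = matrix.values[:, 0::2]
    fractions = (npeaks >= 1).mean(axis=0)
    retained = [l for l, frac in zip(ordered, fractions) if frac > min_fraction]
    if not retained:
        raise ValidationError(
            "prevalence filter removed every locus; review min_fraction "
            f"(={min_fraction}) or input coverage"
        )
    return [
        MsiLocus(l.chrom, l.start, l.end, l.name, i, l.repeat_unit)
        for i, l in enumerate(retained)
    ]


def subset_matrix(matrix: FeatureMatrix, loci: Sequence[MsiLocus]) -> FeatureMatrix:
    """Project a feature matrix onto a (re-indexed) subset of its loci."""
    col_of = {name: j for j, name in enumerate(matrix.locus_names)}
    ordered = sorted(loci, key=lambda l: l.feature_index)
    cols: list[int] = []
    for locus in ordered:
        if locus.name not in col_of:
            raise ValidationError(f"locus {locus.name!r} absent from feature matrix")
        j = col_of[locus.name]
        cols.extend([2 * j, 2 * j + 1])
    values = matrix.values[:, cols]
    callable_loci = (values[:, 0::2] >= 1).sum(axis=1)
    return FeatureMatrix(
        list(matrix.sample_ids), [l.name for l in ordered], values, callable_loci
    )
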