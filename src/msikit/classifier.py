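"""k-means centroid classifier with an inconclusive decision zone.

The caller models the training cohort as k = 3 clusters over the 2L
feature space: two clusters absorb the wide spread of MSI-H samples and
one tight cluster holds MSS together with normal tissue.  A new sample is
assigned the label of its nearest centroid by Euclidean distance, and a
signed decision statistic

    D = d(x, c_MSS) - d(x, c_MSI-H*)

(where c_MSI-H* is the nearer of the two MSI-H centroids) places the
sample relative to the MSS/MSI-H boundary: positive D favors MSI-H.
Samples with |D| < tau (tau = 3.0 by default) fall in the inconclusive
zone and are reported as Inconclusive rather than risk a false call near
the boundary; exactly +/-tau is conclusive.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_io import (
    INCONCLUSIVE,
    MODEL_FORMAT_VERSION,
    MSI_H,
    MSS,
    NORMAL,
    MsiKitError,
    ValidationError,
)
from .features import FeatureMatrix

log = logging.getLogger(__name__)


class TrainingError(MsiKitError):
    """k-means training could not produce a valid centroid model."""


@dataclass
class CentroidModel:
    """Trained k-means centroids with cluster labels and decision threshold.

    ``msih_reference`` selects which MSI-H centroid anchors the decision
    statistic: "nearest" (default) uses the nearer of the MSI-H centroids;
    "first" always uses the lowest-indexed MSI-H cluster.
    """

    k: int
    centroids: np.ndarray           # (k, 2L)
    cluster_labels: list[str]       # per-cluster, exactly one MSS
    loci: list[str]                 # ordered locus names
    tau: float = 3.0
    seed: int | None = None
    restarts: int = 25
    inertia: float | None = None
    msih_reference: str = "nearest"
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (self.k, 2 * len(self.loci)):
            raise ValidationError(
                f"centroid array shape {self.centroids.shape} != "
                f"({self.k}, {2 * len(self.loci)})"
            )
        if len(self.cluster_labels) != self.k:
            raise ValidationError("one label required per cluster")
        if self.cluster_labels.count(MSS) != 1:
            raise ValidationError(
                f"exactly one cluster must be labeled {MSS}; got {self.cluster_labels}"
            )
        if self.tau <= 0:
            raise ValidationError(f"tau must be positive, got {self.tau}")
        if self.msih_reference not in ("nearest", "first"):
            raise ValidationError(f"unknown msih_reference {self.msih_reference!r}")

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]

    @property
    def mss_index(self) -> int:
        return self.cluster_labels.index(MSS)

    @property
    def msih_indices(self) -> list[int]:
        return [i for i, lab in enumerate(self.cluster_labels) if lab == MSI_H]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Apply the (optional) training z-scaling to a vector or matrix."""
        x = np.asarray(x, dtype=float)
        if self.scale_mean is None:
            return x
        return (x - self.scale_mean) / self.scale_sd

    def to_dict(self) -> dict:
        payload = {
            "version": MODEL_FORMAT_VERSION,
            "k": self.k,
            "tau": self.tau,
            "loci": list(self.loci),
            "centroids": self.centroids.tolist(),
            "cluster_labels": list(self.cluster_labels),
            "seed": self.seed,
            "restarts": self.restarts,
            "inertia": self.inertia,
            "msih_reference": self.msih_reference,
        }
        if self.scale_mean is not None:
            payload["scale_mean"] = self.scale_mean.tolist()
            payload["scale_sd"] = self.scale_sd.tolist()
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "CentroidModel":
        required = {"k", "tau", "loci", "centroids", "cluster_labels"}
        missing = required - payload.keys()
        if missing:
            raise ValidationError(f"model payload missing field(s): {sorted(missing)}")
        return cls(
            k=int(payload["k"]),
            centroids=np.asarray(payload["centroids"], dtype=float),
            cluster_labels=list(payload["cluster_labels"]),
            loci=list(payload["loci"]),
            tau=float(payload["tau"]),
            seed=payload.get("seed"),
            restarts=int(payload.get("restarts", 25)),
            inertia=payload.get("inertia"),
            msih_reference=payload.get("msih_reference", "nearest"),
            scale_mean=(
                np.asarray(payload["scale_mean"], dtype=float)
                if payload.get("scale_mean") is not None else None
            ),
            scale_sd=(
                np.asarray(payload["scale_sd"], dtype=float)
                if payload.get("scale_sd") is not None else None
            ),
        )


@dataclass(frozen=True)
class MsiCall:
    """Per-sample classification with its decision statistic and distances."""

    sample_id: str
    label: str                      # MSI-H | MSS | Inconclusive
    nearest_cluster: int
    distances: tuple[float, ...]    # per-centroid Euclidean distances
    decision_d: float


def _normalize_truth(label: str) -> str:
    # Normal tissue clusters with MSS; the model separates MSI-H from the rest.
    return MSS if label == NORMAL else label


def train_kmeans(
    matrix: FeatureMatrix | np.ndarray,
    labels: list[str],
    k: int = 3,
    seed: int | None = 0,
    restarts: int = 25,
    tau: float = 3.0,
    loci: list[str] | None = None,
    scale: bool = False,
    msih_reference: str = "nearest",
) -> CentroidModel:
    """Train the k = 3 centroid model on labeled feature vectors.

    Lloyd's algorithm with Euclidean distance and ``restarts`` seeded
    random-row initializations (lowest within-cluster sum of squares kept).
    Each cluster is then named by the majority gold-standard label of its
    members, with Normal counting toward MSS; training fails unless exactly
    one cluster ends up MSS-labeled.

    ``scale`` optionally z-scores features before clustering (off by
    default: both feature families live on comparable small scales and the
    distances are meant to be read in raw feature units).
    """
    if isinstance(matrix, FeatureMatrix):
        if loci is None:
            loci = list(matrix.locus_names)
        X = matrix.values
    else:
        X = np.asarray(matrix, dtype=float)
    if loci is None:
        raise ValidationError("locus names required when training from a bare array")
    if X.ndim != 2 or X.shape[1] != 2 * len(loci):
        raise ValidationError(f"feature matrix must be n x {2 * len(loci)}")
    n = X.shape[0]
    if len(labels) != n:
        raise ValidationError(f"{n} samples but {len(labels)} labels")
    if k > n:
        raise TrainingError(f"k = {k} exceeds the {n} available samples")
    if np.unique(X, axis=0).shape[0] < k:
        raise TrainingError(
            f"fewer than k = {k} distinct feature vectors; clustering is degenerate"
        )

    scale_mean = scale_sd = None
    if scale:
        scale_mean = X.mean(axis=0)
        scale_sd = X.std(axis=0)
        scale_sd[scale_sd == 0] = 1.0
        X = (X - scale_mean) / scale_sd

    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)

    truth = [_normalize_truth(lab) for lab in labels]
    cluster_labels: list[str] = []
    compositions: list[Counter] = []
    for c in range(k):
        members = Counter(t for t, a in zip(truth, km.labels_) if a == c)
        compositions.append(members)
        if not members:
            raise TrainingError(f"cluster {c} is empty after convergence")
        cluster_labels.append(members.most_common(1)[0][0])
    if cluster_labels.count(MSS) != 1:
        detail = "; ".join(
            f"cluster {c}: {dict(comp)}" for c, comp in enumerate(compositions)
        )
        raise TrainingError(
            f"expected exactly one {MSS}-majority cluster, got labels "
            f"{cluster_labels} ({detail}); the cohort does not support a "
            "two-MSI-H/one-MSS structure at k = 3"
        )

    log.info(
        "trained k=%d model: inertia %.3f, cluster labels %s",
        k, km.inertia_, cluster_labels,
    )
    return CentroidModel(
        k=k,
        centroids=km.cluster_centers_,
        cluster_labels=cluster_labels,
        loci=list(loci),
        tau=tau,
        seed=seed,
        restarts=restarts,
        inertia=float(km.inertia_),
        msih_reference=msih_reference,
        scale_mean=scale_mean,
        scale_sd=scale_sd,
    )


def _distances(x: np.ndarray, model: CentroidModel) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.dim:
        raise ValidationError(
            f"feature vector has dimension {x.shape[0]}, model expects {model.dim}"
        )
    return np.linalg.norm(model.centroids - model.transform(x), axis=1)


def decision_statistic(x: np.ndarray, model: CentroidModel) -> float:
    """Signed distance statistic D = d(x, c_MSS) - d(x, c_MSI-H*).

    Positive D means the sample sits closer to the MSI-H side.  With
    ``msih_reference="first"`` the lowest-indexed MSI-H centroid is used
    instead of the nearer one.
    """
    dists = _distances(x, model)
    msih = model.msih_indices
    if model.msih_reference == "first":
        d_msih = dists[msih[0]]
    else:
        d_msih = dists[msih].min()
    return float(dists[model.mss_index] - d_msih)


def classify(x: np.ndarray, model: CentroidModel, sample_id: str = "") -> MsiCall:
    """Classify one feature vector.

    The nearest centroid (ties -> lower cluster index) is recorded; the
    label is Inconclusive when |D| < tau, else MSI-H for D >= tau and MSS
    for D <= -tau.
    """
    dists = _distances(x, model)
    nearest = int(np.argmin(dists))  # np.argmin already breaks ties low
    d = decision_statistic(x, model)
    # open interval: exactly +/-tau is conclusive
    if d >= model.tau:
        label = MSI_H
    elif d <= -model.tau:
        label = MSS
    else:
        label = INCONCLUSIVE
    return MsiCall(
        sample_id=sample_id,
        label=label,
        nearest_cluster=nearest,
        distances=tuple(float(v) for v in dists),
        decision_d=d,
    )


def classify_cohort(
    matrix: FeatureMatrix | np.ndarray,
    model: CentroidModel,
    sample_ids: list[str] | None = None,
) -> list[MsiCall]:
    """Row-wise classification of a cohort, order preserved."""
    if isinstance(matrix, FeatureMatrix):
        if sample_ids is None:
            sample_ids = matrix.sample_ids
        X = matrix.values
    else:
        X = np.asarray(matrix, dtype=float)
        if X.size == 0:
            return []
        if sample_ids is None:
            sample_ids = [f"sample_{i}" for i in range(X.shape[0])]
    calls = [classify(X[i], model, sid) for i, sid in enumerate(sample_ids)]
    tally = Counter(c.label for c in calls)
    log.info(
        "classified %d samples: %d MSI-H, %d MSS, %d inconclusive",
        len(calls), tally.get(MSI_H, 0), tally.get(MSS, 0), tally.get(INCONCLUSIVE, 0),
    )
    return calls


def write_calls_table(calls: list[MsiCall], path) -> None:
    """Write per-sample calls as TSV: label, decision statistic D and the
    per-centroid distances."""
    if calls:
        k = len(calls[0].distances)
    else:
        k = 0
    cols = ["sample_id", "label", "decision_d"] + [f"d{i + 1}" for i in range(k)] + [
        "nearest_cluster"
    ]
    rows = [
        [c.sample_id, c.label, c.decision_d, *c.distances, c.nearest_cluster]
        for c in calls
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_calls_table(path) -> list[MsiCall]:
    """Read a calls TSV back into :class:`MsiCall` objects."""
    df = pd.read_csv(path, sep="\t")
    dist_cols = sorted(
        (c for c in df.columns if c.startswith("d") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    calls = []
    for _, row in df.iterrows():
        calls.append(
            MsiCall(
                sample_id=str(row["sample_id"]),
                label=str(row["label"]),
                nearest_cluster=int(row["nearest_cluster"]),
                distances=tuple(float(row[c]) for c in dist_cols),
                decision_d=float(row["decision_d"]),
            )
        )
    return calls
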