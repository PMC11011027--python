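"""Query-gallery retrieval evaluation: CMC (Rank-k) and mAP.

Every image of the evaluation pool serves in turn as the query against
all remaining images (self-exclusion by image id only).  Gallery items
are ranked by ascending Euclidean distance between descriptors — i.e.
descending similarity — with ties broken stably by gallery index.

Rank-k is the fraction of queries whose top-k contains at least one
same-identity image.  Average precision for a query is the mean over its
relevant gallery items of the precision at each item's rank (the re-ID
convention, not the interpolated 11-point form); mAP averages this over
queries.  Queries with no same-identity gallery item are excluded with a
warning and reported in the returned count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "GallerySet",
    "RankingResult",
    "EvalReport",
    "euclidean_distance",
    "match_indicator",
    "rank_gallery",
    "rank_all",
    "cmc_at_k",
    "cmc_curve",
    "mean_average_precision",
    "evaluate_descriptors",
    "evaluate",
]


@dataclass
class GallerySet:
    descriptors: np.ndarray            # (N, D)
    labels: np.ndarray                 # (N,) identity ids
    image_ids: list                    # N unique keys

    def __post_init__(self):
        self.descriptors = np.asarray(self.descriptors, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.descriptors.ndim != 2:
            raise ValueError("descriptors must be a 2-D N x D matrix")
        n = self.descriptors.shape[0]
        if len(self.labels) != n or len(self.image_ids) != n:
            raise ValueError("descriptors, labels and image_ids disagree in length")
        if len(set(self.image_ids)) != n:
            raise ValueError("gallery image_ids must be unique")


@dataclass
class RankingResult:
    query_id: object
    order: np.ndarray                  # gallery indices, best match first
    distances: np.ndarray              # ascending


@dataclass
class EvalReport:
    mAP: float
    cmc: np.ndarray                    # cmc[k-1] = Rank-k accuracy
    n_queries: int
    n_excluded: int = 0

    @property
    def rank1(self) -> float:
        return float(self.cmc[0])

    @property
    def rank5(self) -> float:
        return float(self.cmc[4]) if len(self.cmc) >= 5 else float(self.cmc[-1])

    def summary(self) -> str:
        return (f"queries={self.n_queries}  mAP={self.mAP:.4f}  "
                f"Rank-1={self.rank1:.4f}  Rank-5={self.rank5:.4f}")


def euclidean_distance(a, b) -> float:
    """sqrt((A-B).(A-B)) between two descriptor vectors."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"descriptor lengths differ: {a.shape} vs {b.shape}")
    d = a - b
    return float(np.sqrt(d @ d))


def match_indicator(l_image, l_gallery) -> int:
    """1 iff the two identity labels are equal."""
    return int(l_image == l_gallery)


def rank_gallery(query_descriptor, query_image_id, gallery: GallerySet) -> RankingResult:
    """Rank all admissible gallery items for one query.

    The query's own image (matched by image id) is excluded; remaining
    items are sorted by ascending distance, ties kept in gallery order.
    """
    q = np.asarray(query_descriptor, dtype=np.float64).ravel()
    if q.shape[0] != gallery.descriptors.shape[1]:
        raise ValueError(f"query descriptor length {q.shape[0]} does not match "
                         f"gallery dimension {gallery.descriptors.shape[1]}")
    admissible = np.array([i for i, iid in enumerate(gallery.image_ids)
                           if iid != query_image_id])
    if admissible.size == 0:
        raise ValueError("gallery is empty after excluding the query's own image")
    d = np.sqrt(((gallery.descriptors[admissible] - q) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")
    return RankingResult(query_image_id, admissible[order], d[order])


def rank_all(query_descriptors: np.ndarray, query_image_ids,
             gallery: GallerySet) -> list[RankingResult]:
    """Vectorised ranking of many queries against one gallery."""
    qd = np.asarray(query_descriptors, dtype=np.float64)
    dmat = cdist(qd, gallery.descriptors)
    out = []
    gal_ids = gallery.image_ids
    for qi, qid in enumerate(query_image_ids):
        admissible = np.array([i for i, iid in enumerate(gal_ids) if iid != qid])
        if admissible.size == 0:
            raise ValueError("gallery is empty after excluding the query's own image")
        d = dmat[qi, admissible]
        order = np.argsort(d, kind="stable")
        out.append(RankingResult(qid, admissible[order], d[order]))
    return out


def _first_hit_ranks(rankings, query_labels, gallery_labels) -> np.ndarray:
    """1-based rank of the first same-identity item per query (inf if none)."""
    hits = np.full(len(rankings), np.inf)
    for i, (rr, ql) in enumerate(zip(rankings, query_labels)):
        rel = np.flatnonzero(np.asarray(gallery_labels)[rr.order] == ql)
        if rel.size:
            hits[i] = rel[0] + 1
    return hits


def _valid_hits(rankings, query_labels, gallery_labels) -> np.ndarray:
    """First-hit ranks over queries that have >= 1 same-identity item.

    A ranking covers the whole admissible gallery, so an infinite first-hit
    rank occurs exactly when the query has no relevant item at all; such
    queries are excluded from CMC (as from mAP)."""
    hits = _first_hit_ranks(rankings, query_labels, gallery_labels)
    hits = hits[np.isfinite(hits)]
    if hits.size == 0:
        raise ValueError("no query had any same-identity gallery item")
    return hits


def cmc_at_k(rankings, query_labels, gallery_labels, k: int) -> float:
    """Fraction of queries with a same-identity item in the top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = _valid_hits(rankings, query_labels, gallery_labels)
    return float(np.mean(hits <= k))


def cmc_curve(rankings, query_labels, gallery_labels,
              max_k: int | None = None) -> np.ndarray:
    hits = _valid_hits(rankings, query_labels, gallery_labels)
    if max_k is None:
        max_k = max(len(r.order) for r in rankings)
    return np.array([np.mean(hits <= k) for k in range(1, max_k + 1)])


def mean_average_precision(rankings, query_labels,
                           gallery_labels) -> tuple[float, int]:
    """Re-ID mAP; returns (mAP, number of excluded zero-relevant queries)."""
    gallery_labels = np.asarray(gallery_labels)
    aps = []
    excluded = 0
    for rr, ql in zip(rankings, query_labels):
        rel = np.flatnonzero(gallery_labels[rr.order] == ql)
        if rel.size == 0:
            excluded += 1
            continue
        ranks = rel + 1.0                       # 1-based ranks of relevant items
        precision_at = np.arange(1, rel.size + 1) / ranks
        aps.append(precision_at.mean())
    if excluded:
        warnings.warn(f"{excluded} queries had no same-identity gallery item "
                      "and were excluded from mAP", stacklevel=2)
    if not aps:
        raise ValueError("no query had any same-identity gallery item")
    return float(np.mean(aps)), excluded


def evaluate_descriptors(descriptors: np.ndarray, labels, image_ids=None,
                         gallery: GallerySet | None = None,
                         max_k: int | None = None) -> EvalReport:
    """Full evaluation of a descriptor pool.

    With no separate gallery, every image queries the remaining pool
    (the single-pool protocol with self-exclusion).
    """
    descriptors = np.asarray(descriptors, dtype=np.float64)
    labels = np.asarray(labels)
    if image_ids is None:
        image_ids = list(range(len(labels)))
    if gallery is None:
        gallery = GallerySet(descriptors, labels, list(image_ids))
    rankings = rank_all(descriptors, image_ids, gallery)
    m, excluded = mean_average_precision(rankings, labels, gallery.labels)
    cmc = cmc_curve(rankings, labels, gallery.labels, max_k=max_k)
    return EvalReport(mAP=m, cmc=cmc, n_queries=len(rankings) - excluded,
                      n_excluded=excluded)


def evaluate(extractor, images, labels, image_ids=None, batch_size: int = 16,
             max_k: int | None = None) -> EvalReport:
    """Extract descriptors with ``extractor`` (a model or callable mapping an
    image batch to an (N, D) array) and evaluate the single-pool protocol."""
    fn = extractor.extract if hasattr(extractor, "extract") else extractor
    descs = []
    for i in range(0, len(images), batch_size):
        descs.append(np.asarray(fn(images[i:i + batch_size])))
    return evaluate_descriptors(np.concatenate(descs, axis=0), labels,
                                image_ids, max_k=max_k)
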