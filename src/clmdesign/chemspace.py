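"""Chemical-space embedding and the spiked virtual-screening simulation.

The embedding reduces 2048-bit Morgan fingerprints to 50 dimensions by
truncated SVD and projects them to 2D with t-SNE (perplexity 30, Jaccard
distance). The virtual screen ranks a compound library by Tanimoto
similarity to each query molecule, retains the top 1000 per query, and forms
a consensus by averaging ranks across queries — the protocol used to probe
whether de novo designs spiked into a screening library would have been
found by plain similarity searching (high consensus rank = not novel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import TruncatedSVD
from sklearn.manifold import TSNE

from .chem import bulk_tanimoto, fingerprint_matrix


@dataclass(frozen=True)
class EmbeddingConfig:
    """t-SNE settings: SVD target dimensionality, perplexity, metric, seed."""

    svd_dims: int = 50
    perplexity: float = 30.0
    distance_metric: str = "jaccard"
    seed: int = 0
    binarize_svd: bool = True


class ChemicalSpaceEmbedding(BaseEstimator):
    """Truncated-SVD + t-SNE projection of fingerprints to 2D.

    With ``binarize_svd=True`` (default) the Jaccard metric is applied to the
    sign-binarized SVD coordinates; with ``False`` it is applied to the raw
    binary fingerprints directly and the SVD step is skipped for the metric
    (both readings of "Jaccard distance after SVD" are supported).

    Attributes: ``embedding_`` (n, 2) after ``fit``; ``labels_`` mirrors the
    grouping labels passed to ``fit``.
    """

    def __init__(self, svd_dims: int = 50, perplexity: float = 30.0,
                 distance_metric: str = "jaccard", binarize_svd: bool = True, random_state: int = 0):
        self.svd_dims = svd_dims
        self.perplexity = perplexity
        self.distance_metric = distance_metric
        self.binarize_svd = binarize_svd
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: Sequence[str] | None = None):
        """X: (n, 2048) binary fingerprint matrix; y: optional group labels."""
        X = np.asarray(X)
        n = X.shape[0]
        if n <= self.perplexity:
            raise ValueError(f"need more points ({n}) than perplexity ({self.perplexity})")
        dims = min(self.svd_dims, X.shape[1] - 1, n - 1)
        svd = TruncatedSVD(n_components=dims, random_state=self.random_state)
        reduced = svd.fit_transform(X)
        if self.distance_metric == "jaccard":
            # precompute the Jaccard distance matrix on boolean features
            from scipy.spatial.distance import pdist, squareform

            feats = (reduced > 0) if self.binarize_svd else X.astype(bool)
            dist = squareform(pdist(feats, metric="jaccard"))
            tsne = TSNE(
                n_components=2,
                perplexity=self.perplexity,
                metric="precomputed",
                init="random",
                random_state=self.random_state,
            )
            self.embedding_ = tsne.fit_transform(dist)
        else:
            tsne = TSNE(
                n_components=2,
                perplexity=self.perplexity,
                metric=self.distance_metric,
                init="random",
                random_state=self.random_state,
            )
            self.embedding_ = tsne.fit_transform(reduced)
        self.labels_ = list(y) if y is not None else ["all"] * n
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X, y).embedding_

    def to_frame(self, ids: Sequence[str] | None = None) -> pd.DataFrame:
        ids = list(ids) if ids is not None else [str(i) for i in range(len(self.labels_))]
        return pd.DataFrame(
            {"id": ids, "x": self.embedding_[:, 0], "y": self.embedding_[:, 1], "group": self.labels_}
        )


def embed_tsne(smiles: Sequence[str], labels: Sequence[str] | None = None,
               config: EmbeddingConfig = EmbeddingConfig()) -> pd.DataFrame:
    """Fingerprint, reduce, and embed a molecule collection; returns a
    DataFrame (id, x, y, group)."""
    fps = fingerprint_matrix(list(smiles))
    est = ChemicalSpaceEmbedding(
        svd_dims=config.svd_dims,
        perplexity=config.perplexity,
        distance_metric=config.distance_metric,
        binarize_svd=config.binarize_svd,
        random_state=config.seed,
    )
    est.fit(fps, labels)
    return est.to_frame(ids=list(smiles))


@dataclass
class ScreenResult:
    """Per-query top-N rank lists plus the consensus ordering."""

    per_query_ranks: dict[str, pd.DataFrame]
    consensus: pd.DataFrame
    retained_n: int

    def spike_ranks(self, spikes: Sequence[str]) -> pd.DataFrame:
        return self.consensus[self.consensus["id"].isin(list(spikes))].reset_index(drop=True)


def virtual_screen(
    library: Sequence[str],
    spikes: Sequence[str],
    queries: Sequence[str],
    retained_n: int = 1000,
    library_ids: Sequence[str] | None = None,
    spike_ids: Sequence[str] | None = None,
) -> ScreenResult:
    """Similarity screen of ``library`` + ``spikes`` against each query.

    For each query, every library member is ranked by descending Tanimoto
    (ties broken by insertion order) and the top ``retained_n`` are kept.
    The consensus orders members by ascending mean rank across queries;
    members absent from a query's top list are imputed rank
    ``retained_n + 1`` so the mean stays defined for everyone.
    """
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    if len(queries) == 0:
        raise ValueError("queries must be non-empty")
    lib = list(library) + list(spikes)
    ids = list(library_ids) if library_ids is not None else [f"lib{i}" for i in range(len(library))]
    ids += list(spike_ids) if spike_ids is not None else [f"spike{i}" for i in range(len(spikes))]
    fps = fingerprint_matrix(lib)
    qfps = fingerprint_matrix(list(queries))

    n = len(lib)
    per_query: dict[str, pd.DataFrame] = {}
    imputed = retained_n + 1
    mean_ranks = np.zeros(n)
    for qi, q in enumerate(queries):
        sims = bulk_tanimoto(qfps[qi], fps)
        # stable sort on negated similarity keeps insertion order on ties
        order = np.argsort(-sims, kind="stable")
        ranks = np.full(n, imputed, dtype=float)
        top = order[:retained_n]
        ranks[top] = np.arange(1, len(top) + 1)
        mean_ranks += ranks
        per_query[q] = pd.DataFrame(
            {"id": [ids[i] for i in top], "rank": np.arange(1, len(top) + 1), "similarity": sims[top]}
        )
    mean_ranks /= len(queries)
    order = np.argsort(mean_ranks, kind="stable")
    consensus = pd.DataFrame(
        {
            "id": [ids[i] for i in order],
            "consensus_rank": np.arange(1, n + 1),
            "mean_rank": mean_ranks[order],
            "is_spike": [i >= len(library) for i in order],
        }
    )
    return ScreenResult(per_query, consensus, retained_n)
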