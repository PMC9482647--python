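"""The RISynG estimator: recursive integration of synergised
graph-representations for multi-view clustering.

Each view is encoded as a correlation-kernel Gramian G and a shifted
normalised Laplacian L built from a Euclidean heat kernel; the two are fused
per view into a synergy matrix ``H(beta) = beta G + (1 - beta) L`` with beta
chosen by a provisional silhouette scan.  Views are ranked by that
silhouette and merged by a recursive eigenspace update into an n x k
accretive basis, whose rows are clustered with k-means.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .integration import ClusteringResult, cluster_accretive, integrate
from .io import MultiOmicsDataset, OmicsView
from .representations import build_representations
from .synergy import rank_views, select_beta

__all__ = ["RISynG", "risyng_run"]


class RISynG(ClusterMixin, BaseEstimator):
    """Multi-view spectral clustering by recursive synergy integration.

    Parameters
    ----------
    n_clusters : int, default=2
        Number of clusters k; also the dimension of every eigenbasis.
    alpha : float, default=0.1
        Step of the beta scan grid {0, alpha, ..., 1} (11 values at 0.1).
    eig_mode : {"smallest", "largest"}, default="smallest"
        Which end of the synergy spectrum supplies the k-dimensional
        embedding.  With the additive Laplacian shift, cluster indicators
        sit at the bottom of the Laplacian's spectrum and at the top of the
        Gramian's; "smallest" therefore favours the Laplacian
        representation and "largest" the Gramian one (see docs/methods.md).
    scale_factor : float, default=1.0
        Heat-kernel bandwidth as a fraction of the maximum pairwise
        distance; 0.5 halves it.
    gramian_squared : bool, default=False
        Apply the Gramian's exponential factor twice.
    zero_diagonal : bool, default=False
        Remove self-loops from W before building the Laplacian.
    use_shifted_laplacian : bool, default=True
        Combine G with the shifted Laplacian L (default) or with the
        unshifted normalised Laplacian.
    literal_power : bool, default=False
        Use the plain elementwise power in the integration weighting instead
        of the sign-preserving one.
    row_normalize : bool, default=False
        Rescale every residual row to unit length before the attenuating
        power during integration (the fully literal weighting; it lets the
        last-merged view dominate the basis, see integration module).
    reorthonormalize : bool, default=False
        Re-orthonormalise the accretive basis after each merge step.
    kmeans_restarts : int, default=50
        Restarts of the final k-means (the provisional scans use 10).
    t_max : int, default=300
        Maximum k-means iterations.
    random_state : int, default=0
        Master seed; every stochastic step derives a named substream.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster labels, canonicalised by first occurrence.
    embedding_ : ndarray of shape (n_samples, n_clusters)
        The final accretive basis; its rows are the sample embedding.
    view_names_ : list of str
    betas_, silhouettes_ : dict mapping view name -> selected beta /
        provisional silhouette.
    ranks_ : list of view names, most relevant first.

    Examples
    --------
    >>> from risyng.simulate import SyntheticSpec, ViewSpec, make_multiview
    >>> spec = SyntheticSpec(n=60, k=2, cluster_proportions=[0.5, 0.5],
    ...                      views=[ViewSpec(30, 6.0, 1.0, True)], seed=0)
    >>> data, truth = make_multiview(spec)
    >>> model = RISynG(n_clusters=2, random_state=0).fit(data)
    >>> model.labels_.shape
    (60,)
    """

    def __init__(
        self,
        n_clusters: int = 2,
        alpha: float = 0.1,
        eig_mode: str = "smallest",
        scale_factor: float = 1.0,
        gramian_squared: bool = False,
        zero_diagonal: bool = False,
        use_shifted_laplacian: bool = True,
        literal_power: bool = False,
        row_normalize: bool = False,
        reorthonormalize: bool = False,
        kmeans_restarts: int = 50,
        t_max: int = 300,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.alpha = alpha
        self.eig_mode = eig_mode
        self.scale_factor = scale_factor
        self.gramian_squared = gramian_squared
        self.zero_diagonal = zero_diagonal
        self.use_shifted_laplacian = use_shifted_laplacian
        self.literal_power = literal_power
        self.row_normalize = row_normalize
        self.reorthonormalize = reorthonormalize
        self.kmeans_restarts = kmeans_restarts
        self.t_max = t_max
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        if not (isinstance(self.n_clusters, numbers.Integral) and self.n_clusters >= 2):
            raise ValueError(f"n_clusters must be an integer >= 2, got {self.n_clusters}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.eig_mode not in ("smallest", "largest"):
            raise ValueError("eig_mode must be 'smallest' or 'largest'")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.kmeans_restarts < 1:
            raise ValueError("kmeans_restarts must be >= 1")

    @staticmethod
    def _as_views(X) -> list[OmicsView]:
        """Accept a MultiOmicsDataset, a list of OmicsView, or a list of
        (n_samples, n_features) arrays."""
        if isinstance(X, MultiOmicsDataset):
            return list(X.views)
        if isinstance(X, OmicsView):
            return [X]
        if isinstance(X, np.ndarray) and X.ndim == 2:
            X = [X]
        views = []
        n_ref = None
        for m, item in enumerate(X):
            if isinstance(item, OmicsView):
                view = item
            else:
                arr = np.asarray(item, dtype=float)
                if arr.ndim != 2:
                    raise ValueError(f"view {m}: expected a 2-D array")
                if not np.isfinite(arr).all():
                    raise ValueError(f"view {m}: non-finite entries")
                n = arr.shape[0]
                view = OmicsView(
                    name=f"view{m}",
                    X=arr.T,  # estimator API is samples x features
                    feature_ids=[f"f{i}" for i in range(arr.shape[1])],
                    sample_ids=[f"s{i}" for i in range(n)],
                )
            if n_ref is None:
                n_ref = view.n_samples
            elif view.n_samples != n_ref:
                raise ValueError(
                    f"view {view.name!r}: {view.n_samples} samples, expected {n_ref}"
                )
            views.append(view)
        if not views:
            raise ValueError("need at least one view")
        if n_ref < 2:
            raise ValueError("need at least two samples")
        return views

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Run the full pipeline on a multi-view dataset.

        Parameters
        ----------
        X : MultiOmicsDataset, list of OmicsView, or list of array-likes of
            shape (n_samples, n_features_m), one per view.
        y : ignored.
        """
        self._validate()
        views = self._as_views(X)
        n = views[0].n_samples
        if n < self.n_clusters:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds the {n} available samples"
            )
        seed = int(self.random_state)

        svs = []
        for view in views:
            rep = build_representations(
                view,
                scale_factor=self.scale_factor,
                gramian_squared=self.gramian_squared,
                zero_diagonal=self.zero_diagonal,
            )
            L = rep.Lmod if self.use_shifted_laplacian else rep.Lnorm
            svs.append(
                select_beta(
                    rep.G,
                    L,
                    k=self.n_clusters,
                    alpha=self.alpha,
                    seed=seed,
                    name=view.name,
                    mode=self.eig_mode,
                )
            )

        ranked = rank_views(svs)
        basis = integrate(
            ranked,
            k=self.n_clusters,
            literal_power=self.literal_power,
            reorthonormalize=self.reorthonormalize,
            row_normalize=self.row_normalize,
        )
        labels = cluster_accretive(
            basis.b,
            k=self.n_clusters,
            seed=seed,
            restarts=self.kmeans_restarts,
            t_max=self.t_max,
        )

        self.labels_ = labels
        self.embedding_ = basis.b
        self.view_names_ = [v.name for v in views]
        self.betas_ = {sv.name: sv.beta for sv in svs}
        self.silhouettes_ = {sv.name: sv.silhouette for sv in svs}
        self.ranks_ = [sv.name for sv in ranked]
        self.n_views_ = len(views)
        self.sample_ids_ = list(views[0].sample_ids)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def risyng_run(
    data: MultiOmicsDataset,
    k: int,
    config: dict | None = None,
) -> ClusteringResult:
    """Functional entry point: run RISynG on a preprocessed dataset.

    ``config`` holds estimator keyword overrides (``alpha``, ``eig_mode``,
    ``seed``/``random_state``, ...).  Returns a :class:`ClusteringResult`
    with the labels, the final basis and per-view diagnostics.
    """
    params = dict(config or {})
    seed = int(params.pop("seed", params.pop("random_state", 0)))
    model = RISynG(n_clusters=k, random_state=seed, **params).fit(data)
    per_view = [
        {
            "name": name,
            "beta": model.betas_[name],
            "silhouette": model.silhouettes_[name],
            "rank": model.ranks_.index(name) + 1,
        }
        for name in model.view_names_
    ]
    counts = np.bincount(model.labels_, minlength=k)
    return ClusteringResult(
        labels=model.labels_,
        b_final=model.embedding_,
        per_view=per_view,
        k=k,
        seed=seed,
        empty_clusters=bool((counts == 0).any()),
    )
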