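"""Phylogenetic generalized least squares with a Pagel's-lambda structure.

Under Brownian trait evolution on a rooted tree with branch lengths, the
covariance of two tips is proportional to the shared path length from the
root to their most recent common ancestor.  Pagel's lambda scales the
off-diagonal entries of that matrix: lambda = 1 is pure Brownian structure,
lambda = 0 is phylogenetic independence (a star tree).  PGLS fits a linear
regression whose residuals carry this covariance; lambda can be fixed or
profiled by maximum likelihood on [0, 1].

The model is exposed statsmodels-style: build a :class:`PhylogeneticGLS`
from arrays (or :meth:`~PhylogeneticGLS.from_dataframe`), call
:meth:`~PhylogeneticGLS.fit`, and read estimates, standard errors,
``rsquared``, ``lam``, ``llf`` and ``aicc`` off the returned
:class:`PhylogeneticGLSResults`; ``summary()`` prints the usual table.

Regressions are routinely fitted through the origin when the slope itself
is the quantity of interest (a slope of 1 means the predictor method is
unbiased for the response method); ``r^2`` is then defined in the
uncentered V-metric, since a centered total sum of squares is incoherent
without an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "Phylogeny",
    "phylo_vcv",
    "lambda_transform",
    "PhylogeneticGLS",
    "PhylogeneticGLSResults",
    "gls_fit",
    "fit_pgls_ml",
    "aicc_from_loglik",
]


class InvalidTreeError(ValueError):
    """Tree violates PGLS requirements (negative lengths, duplicate tips...)."""


@dataclass(frozen=True)
class Phylogeny:
    """Rooted tree with branch lengths, thin wrapper over a dendropy Tree."""

    tree: dendropy.Tree

    def __post_init__(self):
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise InvalidTreeError(f"duplicate tip labels: {dupes}")
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue  # root edge length is optional
            length = node.edge.length
            who = node.taxon.label if node.taxon else "an internal node"
            if length is None:
                raise InvalidTreeError(f"missing branch length above {who}")
            if length < 0:
                raise InvalidTreeError(
                    f"negative branch length {length} above {who}"
                )

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except dendropy.utility.error.DataParseError as exc:
            raise InvalidTreeError(f"could not parse Newick tree: {exc}") from exc
        return cls(tree)

    @property
    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())


def phylo_vcv(phylogeny: Phylogeny):
    """Brownian-expectation covariance matrix of the tips.

    ``V[i, j]`` is the sum of branch lengths from the root to the most
    recent common ancestor of tips i and j; the diagonal holds root-to-tip
    distances.  Returns ``(V, tip_labels)`` with rows/columns in
    ``tip_labels`` order.
    """
    tree = phylogeny.tree
    labels = phylogeny.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))

    # depth of each node from the root, missing root edge length counts as 0
    depth = {}
    for node in tree.preorder_node_iter():
        elen = node.edge.length or 0.0
        depth[node] = (depth[node.parent_node] if node.parent_node else 0.0) + elen

    # postorder: record tip sets; at each internal node, tip pairs split
    # across different children share exactly that node's depth
    tips_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tips_below[node] = [i]
            V[i, i] = depth[node]
        else:
            children = [tips_below[c] for c in node.child_nodes()]
            d = depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            V[i, j] = V[j, i] = d
            tips_below[node] = [i for ch in children for i in ch]
    return V, labels


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Multiply the off-diagonal entries of V by lambda; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    Vl = lam * np.asarray(V, dtype=float)
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def aicc_from_loglik(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


class PhylogeneticGLS:
    """Linear regression with phylogenetically structured residuals.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response values, one per tip.
    exog : array-like, shape (n,) or (n, p)
        Predictor(s).  An intercept column is added automatically unless
        ``through_origin`` is set.
    tree : Phylogeny, optional
        Phylogeny whose tips match ``tip_labels``; used to build the
        Brownian covariance.  Either ``tree`` or ``vcv`` is required.
    vcv : ndarray, optional
        Pre-computed tip covariance matrix (overrides ``tree``).
    tip_labels : sequence of str, optional
        Labels aligning rows of ``endog``/``exog`` with the covariance.
        Required with ``tree`` unless the data are already in the tree's
        tip order.
    through_origin : bool
        Fit without an intercept.

    Examples
    --------
    >>> phy = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    >>> model = PhylogeneticGLS([1.0, 1.2, 3.1], [1.0, 1.1, 3.0], tree=phy,
    ...                         tip_labels=["A", "B", "C"], through_origin=True)
    >>> res = model.fit(lam=1.0)
    >>> float(res.params[0])  # doctest: +ELLIPSIS
    1.02...
    """

    def __init__(
        self,
        endog,
        exog,
        *,
        tree: Optional[Phylogeny] = None,
        vcv: Optional[np.ndarray] = None,
        tip_labels: Optional[Sequence[str]] = None,
        through_origin: bool = False,
        exog_names: Optional[Sequence[str]] = None,
    ):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = y.size
        if X.shape[0] != n:
            raise ValueError(f"endog has {n} rows but exog has {X.shape[0]}")

        if vcv is not None:
            V = np.asarray(vcv, dtype=float)
            order = list(tip_labels) if tip_labels is not None else None
        elif tree is not None:
            V, tree_order = phylo_vcv(tree)
            if tip_labels is not None:
                pos = {lab: i for i, lab in enumerate(tree_order)}
                missing = [l for l in tip_labels if l not in pos]
                if missing:
                    raise InvalidTreeError(f"tips absent from tree: {missing}")
                perm = [pos[l] for l in tip_labels]
                V = V[np.ix_(perm, perm)]
                order = list(tip_labels)
            else:
                order = tree_order
        else:
            raise ValueError("provide either tree= or vcv=")
        if V.shape != (n, n):
            raise ValueError(
                f"covariance is {V.shape} but data have {n} rows; "
                "prune or match species first"
            )

        names = list(exog_names) if exog_names else [
            f"x{i + 1}" for i in range(X.shape[1])
        ]
        if not through_origin:
            X = np.column_stack([np.ones(n), X])
            names = ["intercept"] + names

        self.endog = y
        self.exog = X
        self.vcv = V
        self.tip_labels = order
        self.through_origin = through_origin
        self.exog_names = names
        self.nobs = n
        self.dropped_species: list = []

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        y: str,
        x,
        tree: Phylogeny,
        *,
        species: str = "species",
        through_origin: bool = False,
    ) -> "PhylogeneticGLS":
        """Build from a species-keyed trait table and a phylogeny.

        Species names are matched to tree tips after normalising spaces vs
        underscores; rows without a matching tip are dropped (the tree's
        extra tips are ignored by subsetting the covariance).
        """
        xcols = [x] if isinstance(x, str) else list(x)
        norm = lambda s: str(s).strip().replace("_", " ")
        tipset = {norm(l): l for l in tree.tip_labels}
        keep = data[data[species].map(lambda s: norm(s) in tipset)]
        dropped = sorted(set(data[species]) - set(keep[species]))
        if keep.empty:
            raise InvalidTreeError("no species in the table match the tree tips")
        labels = [tipset[norm(s)] for s in keep[species]]
        model = cls(
            keep[y].to_numpy(float),
            keep[xcols].to_numpy(float),
            tree=tree,
            tip_labels=labels,
            through_origin=through_origin,
            exog_names=xcols,
        )
        model.dropped_species = dropped
        return model

    # ---- likelihood machinery -------------------------------------------

    def _whiten(self, lam: float):
        Vl = lambda_transform(self.vcv, lam)
        try:
            L = linalg.cholesky(Vl, lower=True)
        except linalg.LinAlgError:
            # numerically singular (e.g. effectively identical tips from
            # zero-length terminal branches): retry with a tiny ridge
            ridge = 1e-10 * float(np.mean(np.diag(Vl)))
            try:
                L = linalg.cholesky(Vl + ridge * np.eye(Vl.shape[0]), lower=True)
            except linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"lambda-transformed covariance not positive definite at "
                    f"lambda={lam}: {exc}"
                ) from exc
        z = linalg.solve_triangular(L, self.endog, lower=True)
        W = linalg.solve_triangular(L, self.exog, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        return z, W, logdet

    def _profile(self, lam: float, reml: bool = False):
        """GLS estimates and profile log-likelihood at fixed lambda."""
        n, p = self.nobs, self.exog.shape[1]
        z, W, logdetV = self._whiten(lam)
        beta, _, rank, _ = np.linalg.lstsq(W, z, rcond=None)
        if rank < p:
            raise np.linalg.LinAlgError(
                f"design matrix rank {rank} < {p}: collinear predictors "
                f"(condition number {np.linalg.cond(W):.3g})"
            )
        resid = z - W @ beta
        rss = float(resid @ resid)
        with np.errstate(divide="ignore"):  # rss == 0 for an exact fit
            if reml:
                sigma2 = rss / (n - p)
                _, logdet_xtx = np.linalg.slogdet(W.T @ W)
                llf = -0.5 * (
                    (n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                    + logdetV
                    + logdet_xtx
                )
            else:
                sigma2 = rss / n
                llf = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdetV)
        return beta, rss, float(llf), z, W, logdetV

    def loglik(self, lam: float, *, reml: bool = False) -> float:
        """Profile log-likelihood of lambda (beta and sigma^2 maximised out)."""
        return self._profile(lam, reml)[2]

    def fit(
        self,
        lam: Optional[float] = None,
        *,
        reml: bool = False,
        k_params: Optional[int] = None,
    ) -> "PhylogeneticGLSResults":
        """Fit the regression; profile lambda by ML/REML when not given.

        Parameters
        ----------
        lam : float, optional
            Fix Pagel's lambda at this value; ``None`` (default) estimates
            it by bounded scalar optimisation on [0, 1] with explicit
            endpoint checks.
        reml : bool
            Profile the restricted likelihood instead of the full ML.
        k_params : int, optional
            Parameter count for AICc.  Defaults to the regression
            coefficients plus one for sigma^2 plus (if profiled) one for
            lambda — the usual comparative-methods accounting; override to
            match other conventions.
        """
        lambda_profiled = lam is None
        if lambda_profiled:
            neg = lambda l: -self.loglik(l, reml=reml)
            res = optimize.minimize_scalar(
                neg, bounds=(0.0, 1.0), method="bounded",
                options={"xatol": 1e-8},
            )
            candidates = [(neg(0.0), 0.0), (neg(1.0), 1.0), (res.fun, float(res.x))]
            _, lam_hat = min(candidates, key=lambda t: t[0])
        else:
            lam_hat = float(lam)

        beta, rss, llf, z, W, _ = self._profile(lam_hat, reml)
        n, p = self.nobs, self.exog.shape[1]
        sigma2_hat = rss / (n - p) if n > p else np.nan
        xtx_inv = np.linalg.inv(W.T @ W)
        bse = np.sqrt(np.diag(sigma2_hat * xtx_inv))

        # r^2 in the V metric: uncentered through the origin, otherwise about
        # the GLS-weighted mean of the response
        if self.through_origin:
            tss = float(z @ z)
        else:
            one_w = W[:, 0]  # whitened intercept column
            mu = float(one_w @ z) / float(one_w @ one_w)
            tss = float((z - mu * one_w) @ (z - mu * one_w))
        rsquared = 1.0 - rss / tss if tss > 0 else np.nan

        k = k_params if k_params is not None else p + 1 + (1 if lambda_profiled else 0)
        aicc = aicc_from_loglik(llf, k, n) if n - k - 1 > 0 else float("nan")
        return PhylogeneticGLSResults(
            model=self,
            params=beta,
            bse=bse,
            lam=lam_hat,
            lambda_profiled=lambda_profiled,
            rss=rss,
            sigma2=sigma2_hat,
            llf=llf,
            reml=reml,
            rsquared=float(rsquared),
            k_params=k,
            aicc=aicc,
            cov_params=sigma2_hat * xtx_inv,
        )


@dataclass
class PhylogeneticGLSResults:
    """Estimates and diagnostics from a :class:`PhylogeneticGLS` fit."""

    model: PhylogeneticGLS
    params: np.ndarray
    bse: np.ndarray
    lam: float
    lambda_profiled: bool
    rss: float
    sigma2: float
    llf: float
    reml: bool
    rsquared: float
    k_params: int
    aicc: float
    cov_params: np.ndarray

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        from scipy import stats

        df = self.nobs - self.model.exog.shape[1]
        return 2.0 * stats.t.sf(np.abs(self.tvalues), df)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy import stats

        df = self.nobs - self.model.exog.shape[1]
        q = stats.t.ppf(1.0 - alpha / 2.0, df)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])

    def lambda_profile(self, grid=None) -> pd.DataFrame:
        """Log-likelihood over a lambda grid (optimiser diagnostics)."""
        grid = np.linspace(0.0, 1.0, 11) if grid is None else np.asarray(grid)
        return pd.DataFrame(
            {"lam": grid, "llf": [self.model.loglik(l, reml=self.reml) for l in grid]}
        )

    def to_dict(self) -> dict:
        names = self.model.exog_names
        out = {
            "n": int(self.nobs),
            "lambda": self.lam,
            "lambda_profiled": self.lambda_profiled,
            "loglik": self.llf,
            "method": "REML" if self.reml else "ML",
            "r2": self.rsquared,
            "k": int(self.k_params),
            "aicc": self.aicc,
            "through_origin": self.model.through_origin,
        }
        for name, b, se in zip(names, self.params, self.bse):
            out[f"coef_{name}"] = float(b)
            out[f"se_{name}"] = float(se)
        return out

    def summary(self) -> str:
        """Plain-text summary table."""
        lines = [
            "Phylogenetic GLS (Pagel's lambda residual structure)",
            "=" * 64,
            f"No. observations: {self.nobs:>6d}    "
            f"lambda: {self.lam:.4f}"
            + (" (ML)" if self.lambda_profiled else " (fixed)"),
            f"Log-likelihood:  {self.llf:>10.3f}    "
            f"AICc (k={self.k_params}): {self.aicc:.3f}",
            f"r-squared:       {self.rsquared:>10.4f}    "
            f"method: {'REML' if self.reml else 'ML'}"
            + ("  [through origin]" if self.model.through_origin else ""),
            "-" * 64,
            f"{'':<14}{'coef':>10}{'std err':>10}{'t':>9}{'P>|t|':>9}",
        ]
        for name, b, se, t, p in zip(
            self.model.exog_names, self.params, self.bse, self.tvalues, self.pvalues
        ):
            lines.append(f"{name:<14}{b:>10.4f}{se:>10.4f}{t:>9.3f}{p:>9.4f}")
        lines.append("=" * 64)
        return "\n".join(lines)


def gls_fit(
    x,
    y,
    V,
    *,
    through_origin: bool = False,
    lam: float = 1.0,
) -> PhylogeneticGLSResults:
    """Functional wrapper: GLS of y on x at a fixed lambda over covariance V."""
    model = PhylogeneticGLS(y, x, vcv=np.asarray(V, float), through_origin=through_origin)
    return model.fit(lam=lam)


def fit_pgls_ml(
    x,
    y,
    tree: Phylogeny,
    *,
    through_origin: bool = False,
    tip_labels: Optional[Sequence[str]] = None,
    reml: bool = False,
) -> PhylogeneticGLSResults:
    """Functional wrapper: PGLS with lambda profiled by maximum likelihood."""
    model = PhylogeneticGLS(
        y, x, tree=tree, tip_labels=tip_labels, through_origin=through_origin
    )
    return model.fit(reml=reml)
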