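"""Rule-based piecewise-linear regression for abundance mapping.

A committee of M5/Cubist-style rule models: each member recursively
partitions the feature space with a shallow, cost-complexity-pruned
regression tree, then builds a linear model in each leaf by greedy forward
selection under a complexity-penalized error, falling back to the leaf mean
when no variable earns its keep. Later committee members are trained on
Quinlan-adjusted targets (2*y - previous prediction) and predictions are
averaged over the committee.

The fit quality statistic is the relative error

    mean |residual| / mean |y - mean(y)|

so a value of 1 corresponds to a mean-only baseline; models at or above 1
fail the usefulness criterion and are flagged. Per-variable attribute usage
is reported as the percentage of training cases whose rule path conditions
on the variable and the percentage whose leaf linear model includes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = ["RuleModel", "fit_abundance_mapper"]


@dataclass
class _Leaf:
    coef: np.ndarray          # over all features (zeros where unused)
    intercept: float
    uses: np.ndarray          # bool mask of features in the linear model


@dataclass
class _Member:
    tree: DecisionTreeRegressor
    leaves: dict[int, _Leaf]


@dataclass
class RuleModel:
    """Fitted committee of piecewise-linear rules."""

    feature_names: list[str]
    members: list[_Member] = field(default_factory=list)
    relative_error: float = np.nan
    attribute_usage: pd.DataFrame | None = None  # var x {conditions, model} in %
    failed: bool = False      # True when relative_error >= 1
    clip: tuple[float, float] | None = None
    target_name: str | None = None

    # -- fitting -----------------------------------------------------------

    @classmethod
    def fit(
        cls,
        X: pd.DataFrame,
        y: np.ndarray,
        n_committees: int = 5,
        max_depth: int = 3,
        min_samples_leaf: int | None = None,
        prune_frac: float = 0.15,
        seed: int = 0,
        clip: tuple[float, float] | None = None,
        target_name: str | None = None,
    ) -> "RuleModel":
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        if n <= d / 2:
            raise ValueError(f"need n_sites > n_variables/2, got n={n}, d={d}")
        model = cls(feature_names=list(X.columns), clip=clip, target_name=target_name)
        Xv = X.to_numpy(dtype=float)
        msl = min_samples_leaf if min_samples_leaf is not None else max(10, n // 6)

        target = y.copy()
        prev_pred = None
        for m in range(n_committees):
            if prev_pred is not None:
                target = 2.0 * y - prev_pred  # Quinlan committee adjustment
            member = model._fit_member(Xv, target, max_depth, msl, prune_frac, seed + m)
            model.members.append(member)
            prev_pred = model._predict_member(member, Xv)

        pred = model._predict_array(Xv)
        denom = np.mean(np.abs(y - y.mean()))
        model.relative_error = (
            1.0 if denom == 0 else float(np.mean(np.abs(y - pred)) / denom)
        )
        model.failed = model.relative_error >= 1.0
        model.attribute_usage = model._compute_usage(Xv)
        return model

    def _fit_member(self, Xv, target, max_depth, msl, prune_frac, seed) -> _Member:
        # cost-complexity pruning scaled to the target variance keeps rules
        # only where a split buys a substantial error reduction, so a pure
        # noise target collapses toward the mean-only baseline
        tree = DecisionTreeRegressor(
            max_depth=max_depth, min_samples_leaf=msl, random_state=seed,
            ccp_alpha=prune_frac * float(np.var(target)),
        )
        tree.fit(Xv, target)
        leaf_of = tree.apply(Xv)
        split_feats = np.unique(
            tree.tree_.feature[tree.tree_.feature >= 0])  # features actually split on
        leaves: dict[int, _Leaf] = {}
        for leaf in np.unique(leaf_of):
            idx = leaf_of == leaf
            leaves[int(leaf)] = self._fit_leaf(
                Xv[idx], target[idx], split_feats)
        return _Member(tree=tree, leaves=leaves)

    def _fit_leaf(self, Xl, yl, candidate_feats) -> _Leaf:
        """Greedy forward selection of a leaf linear model.

        Starting from the leaf mean, features are added one at a time when
        they reduce the complexity-penalized training error
        mean|res| * (n + v + 1)/(n - v - 1); split-path features are tried
        first, then the rest in column order. The mean model wins on noise.
        """
        d = Xl.shape[1]
        nl = len(yl)
        mean_model = _Leaf(np.zeros(d), float(yl.mean()), np.zeros(d, dtype=bool))
        usable = [f for f in range(d) if np.ptp(Xl[:, f]) > 0]
        if not usable or nl < 8:
            return mean_model
        ordered = [f for f in candidate_feats if f in usable] + \
            [f for f in usable if f not in set(candidate_feats)]

        def penalized(residuals, v):
            if nl - v - 1 <= 0:
                return np.inf
            return np.mean(np.abs(residuals)) * (nl + v + 1) / (nl - v - 1)

        chosen: list[int] = []
        best_err = penalized(yl - yl.mean(), 0)
        best_beta = None
        max_feats = min(len(ordered), max(1, nl // 4))
        # each added feature must buy a clear (5%) drop in penalized error;
        # guards against the winner's curse of scanning many candidates
        min_gain = 0.95
        improved = True
        while improved and len(chosen) < max_feats:
            improved = False
            trial_best = (best_err * min_gain, None, None)
            for f in ordered:
                if f in chosen:
                    continue
                feats = chosen + [f]
                A = np.column_stack([np.ones(nl), Xl[:, feats]])
                beta, *_ = np.linalg.lstsq(A, yl, rcond=None)
                err = penalized(yl - A @ beta, len(feats))
                if err < trial_best[0] - 1e-12:
                    trial_best = (err, f, beta)
            if trial_best[1] is not None:
                best_err, f, best_beta = trial_best
                chosen.append(f)
                improved = True
        if not chosen:
            return mean_model
        coef = np.zeros(d)
        coef[chosen] = best_beta[1:]
        uses = np.zeros(d, dtype=bool)
        uses[chosen] = np.abs(best_beta[1:]) > 1e-12
        return _Leaf(coef, float(best_beta[0]), uses)

    # -- prediction --------------------------------------------------------

    def _predict_member(self, member: _Member, Xv: np.ndarray) -> np.ndarray:
        leaf_of = member.tree.apply(Xv)
        out = np.empty(len(Xv))
        for leaf, lm in member.leaves.items():
            idx = leaf_of == leaf
            if idx.any():
                out[idx] = lm.intercept + Xv[idx] @ lm.coef
        # rows routed to leaves unseen in training fall back to the tree mean
        unseen = ~np.isin(leaf_of, list(member.leaves))
        if unseen.any():
            out[unseen] = member.tree.predict(Xv[unseen])
        return out

    def _predict_array(self, Xv: np.ndarray) -> np.ndarray:
        pred = np.mean(
            [self._predict_member(m, Xv) for m in self.members], axis=0)
        if self.clip is not None:
            pred = np.clip(pred, *self.clip)
        return pred

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predict for any frame containing the fitted feature columns;
        invariant to row order."""
        return self._predict_array(X[self.feature_names].to_numpy(dtype=float))

    # -- diagnostics -------------------------------------------------------

    def _compute_usage(self, Xv: np.ndarray) -> pd.DataFrame:
        d = len(self.feature_names)
        cond = np.zeros(d)
        modl = np.zeros(d)
        n = len(Xv)
        for member in self.members:
            t = member.tree.tree_
            node_of = member.tree.decision_path(Xv)
            # conditions: sample passes through a node splitting on the var
            for f in range(d):
                nodes = np.where(t.feature == f)[0]
                if len(nodes):
                    hits = np.asarray(node_of[:, nodes].sum(axis=1)).ravel()
                    cond[f] += (hits > 0).mean()
            leaf_of = member.tree.apply(Xv)
            for leaf, lm in member.leaves.items():
                idx = leaf_of == leaf
                if idx.any():
                    modl[lm.uses] += idx.mean()
        k = len(self.members)
        return pd.DataFrame(
            {"conditions": cond / k * 100.0, "model": modl / k * 100.0},
            index=self.feature_names,
        )

    def uses_variables(self, variables: list[str], tol: float = 0.0) -> bool:
        """Whether any of ``variables`` appears in conditions or leaf models."""
        u = self.attribute_usage
        present = [v for v in variables if v in u.index]
        return bool((u.loc[present].to_numpy() > tol).any()) if present else False


def fit_abundance_mapper(
    env: pd.DataFrame,
    cluster_abund: pd.DataFrame,
    cluster_id: str,
    feature_names: list[str] | None = None,
    seed: int = 0,
    **kwargs,
) -> RuleModel:
    """Fit a rule-based mapper environment -> eco-cluster relative abundance.

    Predictions are clipped to [0, 1] since the target is a relative
    abundance. Models with relative error >= 1 (no better than predicting
    the training mean) are flagged as failing.
    """
    from .synthetic import ENV_VARIABLES

    feats = feature_names or [v for v in ENV_VARIABLES if v in env.columns]
    y = cluster_abund[cluster_id].to_numpy(dtype=float)
    return RuleModel.fit(
        env[feats], y, seed=seed, clip=(0.0, 1.0), target_name=cluster_id, **kwargs
    )
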