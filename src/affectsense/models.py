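"""The model zoo: benchmarks, population learners, MERF, embedding net.

Every estimator follows one contract: ``fit(X, y, groups)`` and
``predict(X, groups=None)``, where ``groups`` carries participant ids.
Population models ignore groups; personalized models use them and define
cold-start behavior for ids unseen at fit time.  Predictions are never
clipped to the 1-7 scale (the benchmarks cannot leave it, and clipping
would silently change error comparisons).
"""

from __future__ import annotations

import copy
import hashlib
import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_X_y, check_array

from .nn import DenseNet, train_dense


def _check_fit(X, y):
    X, y = check_X_y(X, y, ensure_min_samples=1, y_numeric=True)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values; impute before fitting")
    return X, y


class InterceptRegressor(BaseEstimator, RegressorMixin):
    """Intercept-only benchmark: grand mean or per-person mean NA.

    strategy='global' predicts the training grand mean everywhere;
    strategy='per_person' predicts each participant's training mean and
    falls back to the grand mean for unseen participants.  ``adapt``
    returns a copy whose person means are recomputed from adaptation data
    (used for new-user evaluation), keeping the original global fallback.
    """

    def __init__(self, strategy: str = "global"):
        self.strategy = strategy

    def fit(self, X, y, groups=None):
        y = np.asarray(y, float)
        if len(y) == 0:
            raise ValueError("empty training set")
        self.global_mean_ = float(y.mean())
        self.person_means_ = {}
        if self.strategy == "per_person":
            if groups is None:
                raise ValueError("per_person strategy needs groups")
            groups = np.asarray(groups)
            for g in np.unique(groups):
                self.person_means_[g] = float(y[groups == g].mean())
        elif self.strategy != "global":
            raise ValueError("strategy must be 'global' or 'per_person'")
        return self

    def predict(self, X, groups=None):
        n = len(X)
        if self.strategy == "global" or groups is None:
            return np.full(n, self.global_mean_)
        groups = np.asarray(groups)
        return np.array([self.person_means_.get(g, self.global_mean_) for g in groups])

    def adapt(self, y, groups):
        new = copy.deepcopy(self)
        y = np.asarray(y, float)
        groups = np.asarray(groups)
        for g in np.unique(groups):
            new.person_means_[g] = float(y[groups == g].mean())
        return new


class PopulationRegressor(BaseEstimator, RegressorMixin):
    """Wrap any group-agnostic sklearn regressor under the zoo contract."""

    def __init__(self, base=None):
        self.base = base

    def fit(self, X, y, groups=None):
        X, y = _check_fit(X, y)
        self.model_ = clone(self.base)
        self.model_.fit(X, y)
        return self

    def predict(self, X, groups=None):
        return self.model_.predict(check_array(X))


def make_linear():
    return PopulationRegressor(LinearRegression())


def make_forest(n_estimators=100, max_depth=None, random_state=0, **kw):
    return PopulationRegressor(RandomForestRegressor(
        n_estimators=n_estimators, max_depth=max_depth,
        random_state=random_state, n_jobs=1, **kw))


def make_ffnn(hidden=(64, 32), lr=1e-3, max_iter=300, random_state=0):
    return PopulationRegressor(MLPRegressor(
        hidden_layer_sizes=hidden, learning_rate_init=lr, max_iter=max_iter,
        random_state=random_state, early_stopping=False))


class MerfRegressor(BaseEstimator, RegressorMixin):
    """Mixed-effect random forest: global forest + random intercepts.

    Model: y_it = f(x_it) + b_i + e_it with b_i ~ N(0, sigma_b^2) and
    e_it ~ N(0, sigma^2).  Fitted by EM-style alternation:

    1. fit a random forest on (X, y - b_hat[group]);
    2. with residuals r = y - f_hat(X) (out-of-bag predictions on training
       rows when available), update each intercept by BLUP shrinkage
       b_i = rbar_i * sigma_b^2 / (sigma_b^2 + sigma^2 / n_i);
    3. update sigma^2 and sigma_b^2 by the Gaussian EM M-step (posterior
       variances included), which moment-matches the intercept dispersion.

    Iteration stops when the relative change of the penalized Gaussian
    objective falls below ``tol``.  Unseen participants at predict time get
    b = 0 (cold start).  ``fix_sigma2_b=0`` forces all intercepts to zero,
    collapsing the model onto the plain forest.
    """

    def __init__(self, n_estimators=100, max_depth=None, max_iter=8, tol=1e-3,
                 use_oob=True, fix_sigma2_b=None, random_state=0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_iter = max_iter
        self.tol = tol
        self.use_oob = use_oob
        self.fix_sigma2_b = fix_sigma2_b
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        X, y = _check_fit(X, y)
        if groups is None:
            raise ValueError("MERF needs groups")
        groups = np.asarray(groups)
        uniq, gidx = np.unique(groups, return_inverse=True)
        m = len(uniq)
        if m < 2:
            warnings.warn("single participant: MERF degenerates to a plain forest")
        n_i = np.bincount(gidx, minlength=m).astype(float)
        person_means = np.array([y[gidx == i].mean() for i in range(m)])
        b = np.zeros(m)
        sigma2 = float(np.var(y)) or 1.0
        sigma2_b = float(np.var(person_means))
        if self.fix_sigma2_b is not None:
            sigma2_b = float(self.fix_sigma2_b)
        use_oob = self.use_oob and self.n_estimators >= 20
        self.oob_used_ = use_oob
        trace = []
        self.converged_ = False
        for it in range(self.max_iter):
            forest = RandomForestRegressor(
                n_estimators=self.n_estimators, max_depth=self.max_depth,
                random_state=self.random_state, n_jobs=1,
                oob_score=use_oob, bootstrap=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                forest.fit(X, y - b[gidx])
            if use_oob:
                fhat = np.asarray(forest.oob_prediction_, float)
                bad = ~np.isfinite(fhat)
                if bad.any():
                    fhat[bad] = forest.predict(X[bad])
            else:
                fhat = forest.predict(X)
            r = y - fhat
            rbar = np.bincount(gidx, weights=r, minlength=m) / n_i
            if self.fix_sigma2_b is not None and self.fix_sigma2_b == 0:
                b = np.zeros(m)
                post_var = np.zeros(m)
            else:
                shrink = sigma2_b / (sigma2_b + sigma2 / n_i) if sigma2_b > 0 else np.zeros(m)
                b = rbar * shrink
                post_var = (sigma2_b * sigma2 / n_i / (sigma2_b + sigma2 / n_i)
                            if sigma2_b > 0 else np.zeros(m))
            resid = r - b[gidx]
            sigma2 = float((np.sum(resid ** 2) + np.sum(n_i * post_var)) / len(y))
            if self.fix_sigma2_b is None:
                sigma2_b = float(np.mean(b ** 2 + post_var))
            # penalized Gaussian objective (generalized log-likelihood)
            obj = (np.sum(resid ** 2) / sigma2 + len(y) * np.log(sigma2))
            if sigma2_b > 0:
                obj += np.sum(b ** 2) / sigma2_b + m * np.log(sigma2_b)
            trace.append(float(obj))
            self.forest_ = forest
            if it >= 1 and abs(trace[-2] - trace[-1]) <= self.tol * abs(trace[-2]):
                self.converged_ = True
                break
        self.trace_ = trace
        self.n_iter_ = len(trace)
        self.sigma2_eps_ = sigma2
        self.sigma2_b_ = sigma2_b
        self.classes_seen_ = uniq
        self.intercepts_ = {g: float(b[i]) for i, g in enumerate(uniq)}
        if not self.converged_:
            warnings.warn("MERF did not converge; returning last iterate")
        return self

    def predict(self, X, groups=None):
        X = check_array(X)
        pred = self.forest_.predict(X)
        if groups is not None:
            groups = np.asarray(groups)
            pred = pred + np.array([self.intercepts_.get(g, 0.0) for g in groups])
        return pred


class EmbeddingNetRegressor(BaseEstimator, RegressorMixin):
    """Feed-forward net with a learned per-participant embedding vector.

    Each participant id maps to a d-dimensional embedding that is
    concatenated with the block features before the first dense layer;
    embeddings and dense weights are trained jointly on squared error.
    Unseen participants are represented by the mean of the learned
    embedding rows (cold start).  ``finetune_embeddings`` adapts new users:
    fresh rows are created at the mean embedding and optimized on the
    adaptation data while every dense parameter stays bit-identical.
    """

    def __init__(self, d=32, hidden=(64, 32), epochs=300, batch_size=64,
                 lr=5e-3, l2=3e-3, random_state=0):
        self.d = d
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.l2 = l2
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        if self.d <= 0:
            raise ValueError("embedding dimension must be positive")
        X, y = _check_fit(X, y)
        if groups is None:
            raise ValueError("embedding net needs groups")
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        self.id_index_ = {g: i for i, g in enumerate(uniq)}
        rng = np.random.default_rng(self.random_state)
        self.embedding_ = rng.normal(0, 0.1, (len(uniq), self.d))
        self.net_ = DenseNet(self.d + X.shape[1], hidden=self.hidden, rng=rng)
        rows = np.array([self.id_index_[g] for g in groups])
        # train on the centered target; the offset is restored at predict time
        self.y_mean_ = float(np.mean(y))
        self.loss_curve_ = train_dense(
            self.net_, X, y - self.y_mean_, epochs=self.epochs,
            batch_size=self.batch_size, lr=self.lr, l2=self.l2, rng=rng,
            embedding=self.embedding_, group_rows=rows)
        return self

    def _rows_for(self, groups, n):
        if groups is None:
            return None
        mean_row = self.embedding_.mean(axis=0)
        rows = []
        for g in np.asarray(groups):
            rows.append(self.id_index_.get(g, -1))
        return np.asarray(rows), mean_row

    def predict(self, X, groups=None):
        X = check_array(X)
        if groups is None:
            emb = np.tile(self.embedding_.mean(axis=0), (len(X), 1))
        else:
            rows, mean_row = self._rows_for(groups, len(X))
            emb = np.where((rows >= 0)[:, None], self.embedding_[np.clip(rows, 0, None)], mean_row)
        return self.net_.predict(np.concatenate([emb, X], axis=1)) + self.y_mean_

    def dense_param_hash(self) -> str:
        """SHA-256 over all non-embedding parameters (freeze audit)."""
        h = hashlib.sha256()
        for p in self.net_.params():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    def finetune_embeddings(self, X, y, groups, epochs=100, lr=1e-2):
        """Adapt to new users by optimizing only their embedding rows.

        Returns an adapted copy; dense weights and existing users' rows are
        untouched.  New ids must be disjoint from training ids.  An empty
        adaptation set leaves the fresh rows at their mean-embedding
        initialization (with a warning).
        """
        new = copy.deepcopy(self)
        groups = np.asarray(groups)
        new_ids = [g for g in dict.fromkeys(groups.tolist())]
        clash = [g for g in new_ids if g in self.id_index_]
        if clash:
            raise ValueError(f"ids already known at fit time: {clash[:3]}")
        mean_row = new.embedding_.mean(axis=0)
        start = len(new.embedding_)
        for i, g in enumerate(new_ids):
            new.id_index_[g] = start + i
        new.embedding_ = np.vstack([new.embedding_] + [mean_row[None, :]] * len(new_ids))
        if len(X) == 0:
            warnings.warn("empty adaptation set; embeddings stay at initialization")
            return new
        X = check_array(X)
        y = np.asarray(y, float)
        rows = np.array([new.id_index_[g] for g in groups])
        rng = np.random.default_rng(self.random_state + 17)
        train_dense(new.net_, X, y - self.y_mean_, epochs=epochs,
                    batch_size=self.batch_size, lr=lr, l2=0.0, rng=rng,
                    embedding=new.embedding_, group_rows=rows,
                    trainable_rows=np.arange(start, len(new.embedding_)),
                    freeze_dense=True)
        return new


def save_model(model, path_prefix) -> None:
    """Persist a zoo model: JSON metadata plus a weight blob where needed.

    Intercept models are pure JSON.  MERF writes variance components and
    intercepts to JSON and the forest to a joblib blob; networks write
    their arrays to an .npz blob.
    """
    import json
    from pathlib import Path

    import joblib

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = {"class": type(model).__name__, "params": model.get_params()}
    if isinstance(model, PopulationRegressor):
        # the wrapped estimator lives in the blob; record only its repr
        meta["params"] = {"base": repr(model.base)}
    if isinstance(model, InterceptRegressor):
        meta["global_mean"] = model.global_mean_
        meta["person_means"] = {str(k): v for k, v in model.person_means_.items()}
    elif isinstance(model, MerfRegressor):
        meta["sigma2_eps"] = model.sigma2_eps_
        meta["sigma2_b"] = model.sigma2_b_
        meta["intercepts"] = {str(k): v for k, v in model.intercepts_.items()}
        meta["trace"] = model.trace_
        meta["converged"] = model.converged_
        joblib.dump(model.forest_, prefix.with_suffix(".forest.joblib"))
    elif isinstance(model, EmbeddingNetRegressor):
        meta["id_index"] = {str(k): int(v) for k, v in model.id_index_.items()}
        meta["y_mean"] = model.y_mean_
        arrays = {"embedding": model.embedding_}
        for i, (W, b) in enumerate(zip(model.net_.W, model.net_.b)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(prefix.with_suffix(".weights.npz"), **arrays)
    elif isinstance(model, PopulationRegressor):
        joblib.dump(model.model_, prefix.with_suffix(".model.joblib"))
    else:
        raise TypeError(f"unknown model type {type(model).__name__}")
    with open(prefix.with_suffix(".json"), "w") as f:
        json.dump(meta, f, indent=1)


def load_model(path_prefix):
    """Inverse of :func:`save_model`."""
    import json
    from pathlib import Path

    import joblib

    prefix = Path(path_prefix)
    with open(prefix.with_suffix(".json")) as f:
        meta = json.load(f)
    cls = meta["class"]
    if cls == "InterceptRegressor":
        m = InterceptRegressor(**meta["params"])
        m.global_mean_ = meta["global_mean"]
        m.person_means_ = dict(meta["person_means"])
        return m
    if cls == "MerfRegressor":
        m = MerfRegressor(**meta["params"])
        m.sigma2_eps_ = meta["sigma2_eps"]
        m.sigma2_b_ = meta["sigma2_b"]
        m.intercepts_ = dict(meta["intercepts"])
        m.trace_ = meta["trace"]
        m.converged_ = meta["converged"]
        m.forest_ = joblib.load(prefix.with_suffix(".forest.joblib"))
        return m
    if cls == "EmbeddingNetRegressor":
        m = EmbeddingNetRegressor(**{k: tuple(v) if k == "hidden" else v
                                     for k, v in meta["params"].items()})
        data = np.load(prefix.with_suffix(".weights.npz"))
        m.embedding_ = data["embedding"]
        n_layers = sum(1 for k in data.files if k.startswith("W"))
        net = DenseNet(1, hidden=())
        net.W = [data[f"W{i}"] for i in range(n_layers)]
        net.b = [data[f"b{i}"] for i in range(n_layers)]
        m.net_ = net
        m.id_index_ = dict(meta["id_index"])
        m.y_mean_ = meta["y_mean"]
        return m
    if cls == "PopulationRegressor":
        m = PopulationRegressor()
        m.model_ = joblib.load(prefix.with_suffix(".model.joblib"))
        return m
    raise TypeError(f"unknown model class {cls}")


def fit_intercepts(y, groups):
    """Convenience: fit both benchmark models at once."""
    gi = InterceptRegressor("global").fit(np.zeros((len(y), 1)), y)
    pp = InterceptRegressor("per_person").fit(np.zeros((len(y), 1)), y, groups)
    return gi, pp


def model_registry(random_state: int = 0, small: bool = False) -> dict:
    """The eleven published model configurations.

    Maps display name -> dict(factory, variant, personalized, adapts).
    ``small`` shrinks forests/networks for quick runs.
    """
    trees = 50 if small else 100
    epochs = 200 if small else 300
    iters = 150 if small else 300
    merf_iter = 4 if small else 8

    def spec(factory, variant="passive_only", category="population", adapts=False):
        return {"factory": factory, "variant": variant, "category": category,
                "personalized": category == "personalized", "adapts": adapts}

    def forest_factory(**kw):
        return make_forest(**{"n_estimators": trees, "random_state": random_state, **kw})

    def ffnn_factory(**kw):
        return make_ffnn(**{"max_iter": iters, "random_state": random_state, **kw})

    def merf_factory(**kw):
        return MerfRegressor(**{"n_estimators": trees, "max_iter": merf_iter,
                                "random_state": random_state, **kw})

    def embed_factory(**kw):
        return EmbeddingNetRegressor(**{"d": 32, "epochs": epochs,
                                        "random_state": random_state, **kw})

    return {
        "Global Intercept": spec(lambda **kw: InterceptRegressor("global")),
        "Per Person Intercept": spec(lambda **kw: InterceptRegressor("per_person"),
                                     category="personalized", adapts=True),
        "LR": spec(lambda **kw: make_linear()),
        "RF": spec(forest_factory),
        "FFNN": spec(ffnn_factory),
        "LR + PS": spec(lambda **kw: make_linear(), variant="with_PS",
                        category="ps_augmented"),
        "RF + PS": spec(forest_factory, variant="with_PS", category="ps_augmented"),
        "FFNN + PS": spec(ffnn_factory, variant="with_PS", category="ps_augmented"),
        "MERF": spec(merf_factory, category="personalized"),
        "MERF + PS": spec(merf_factory, variant="with_PS", category="personalized"),
        "FFNN + Embedding": spec(embed_factory, category="personalized", adapts=True),
    }
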