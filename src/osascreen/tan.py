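"""Tree-augmented naive Bayes (TAN) classifier over categorical predictors.

A TAN relaxes naive Bayes by letting every feature depend on the class plus at
most one other feature, the feature-feature edges forming a tree.  Structure is
learned Chow–Liu style: a maximum-weight spanning tree over the complete
feature graph, weighted by class-conditional mutual information (CMI, in bits)
estimated from smoothed empirical counts.  Parameters are Laplace-smoothed
relative frequencies.  Inference is exact: the probability of the class given
any subset of observed features is obtained by marginalizing the factorized
joint over all completions of the missing ones, in log space.

:class:`TANClassifier` follows scikit-learn estimator conventions (``fit`` /
``predict_proba`` / ``get_params``, fitted attributes with a trailing
underscore) and accepts missing evidence as ``None``/NaN/empty cells.  The
module-level functions (:func:`learn_structure`, :func:`fit_parameters`,
:func:`predict_probability`, :func:`save_model`, :func:`load_model`) are thin
wrappers over it.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import MODEL_VARIABLES, VARIABLE_LEVELS, EncodedRecord

__all__ = [
    "TANClassifier",
    "TANStructure",
    "conditional_mutual_information",
    "learn_structure",
    "fit_parameters",
    "predict_probability",
    "save_model",
    "load_model",
]

SCHEMA_VERSION = 1
_MISSING = -1  # integer code for a missing level


@dataclass(frozen=True)
class TANStructure:
    """Learned topology: a directed tree over the features, plus the class.

    Every feature has the class as a parent; every non-root feature has
    exactly one feature parent, so each feature has at most two parents.
    """

    class_variable: str
    feature_order: tuple[str, ...]
    tree_edges: tuple[tuple[str, str], ...]  # (parent, child), oriented away from root
    root_feature: str

    def validate(self) -> None:
        feats = set(self.feature_order)
        if self.root_feature not in feats:
            raise ValueError("root feature not among features")
        if len(self.tree_edges) != len(feats) - 1:
            raise ValueError("a tree over k features needs exactly k-1 edges")
        parent_of: dict[str, str] = {}
        for p, c in self.tree_edges:
            if p not in feats or c not in feats:
                raise ValueError(f"edge ({p},{c}) references unknown feature")
            if c in parent_of:
                raise ValueError(f"feature {c!r} has two feature parents")
            parent_of[c] = p
        if self.root_feature in parent_of:
            raise ValueError("root feature must have no feature parent")
        # connectivity: walk up from every node to the root
        for f in feats:
            seen = set()
            node = f
            while node != self.root_feature:
                if node in seen or node not in parent_of:
                    raise ValueError("tree_edges do not form a tree rooted at root_feature")
                seen.add(node)
                node = parent_of[node]

    def parent_of(self, feature: str) -> str | None:
        for p, c in self.tree_edges:
            if c == feature:
                return p
        return None


def conditional_mutual_information(counts: np.ndarray, alpha: float = 0.0) -> float:
    """Class-conditional mutual information I(X;Y|C) in bits.

    ``counts`` is a 3-way contingency array of shape (|X|, |Y|, |C|); ``alpha``
    is added to every cell before normalizing (same smoothing as parameter
    fitting).  If X or Y has a single observed level the CMI is defined as 0
    and a warning is emitted: smoothing a degenerate margin would manufacture
    spurious dependence.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 3:
        raise ValueError("counts must be a 3-way (X, Y, C) array")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    observed_x = (counts.sum(axis=(1, 2)) > 0).sum()
    observed_y = (counts.sum(axis=(0, 2)) > 0).sum()
    if observed_x < 2 or observed_y < 2:
        warnings.warn("variable with a single observed level: CMI defined as 0", stacklevel=2)
        return 0.0
    p = counts + alpha
    total = p.sum()
    if total == 0:
        return 0.0
    p = p / total
    p_c = p.sum(axis=(0, 1))  # (C,)
    p_xc = p.sum(axis=1)  # (X, C)
    p_yc = p.sum(axis=0)  # (Y, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p * p_c[None, None, :] / (p_xc[:, None, :] * p_yc[None, :, :])
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, ratio, 1.0)), 0.0)
    return float(max(terms.sum(), 0.0))


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _maximum_spanning_tree(
    features: list[str], weights: dict[tuple[str, str], float], root: str
) -> tuple[tuple[str, str], ...]:
    """Deterministic Kruskal: edges sorted by weight desc, then name pair asc."""
    edges = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    uf = _UnionFind(features)
    undirected: list[tuple[str, str]] = []
    for (a, b), _w in edges:
        if uf.union(a, b):
            undirected.append((a, b))
            if len(undirected) == len(features) - 1:
                break
    # orient away from the root (BFS)
    adj: dict[str, list[str]] = {f: [] for f in features}
    for a, b in undirected:
        adj[a].append(b)
        adj[b].append(a)
    directed: list[tuple[str, str]] = []
    seen = {root}
    queue = [root]
    while queue:
        node = queue.pop(0)
        for nb in sorted(adj[node]):
            if nb not in seen:
                seen.add(nb)
                directed.append((node, nb))
                queue.append(nb)
    return tuple(directed)


class TANClassifier(BaseEstimator, ClassifierMixin):
    """Tree-augmented naive Bayes with exact missing-evidence inference.

    Parameters
    ----------
    alpha : float, default=1.0
        Additive (Laplace) smoothing, shared by the CMI edge weights and the
        conditional probability tables.
    levels : dict or None
        Declared levels per feature.  ``None`` uses the standard screening
        variables when the input columns match them, otherwise levels are
        inferred from the training data (sorted).
    root : str or None
        Feature at the root of the tree; ``None`` picks the lexicographically
        smallest name.  The root choice reparameterizes but does not change
        the represented joint distribution.
    class_variable : str, default="osa"
        Name of the class variable (reporting / serialization only).

    Attributes
    ----------
    classes_ : ndarray of the class values (sorted).
    feature_names_in_ : list of feature names.
    levels_ : dict feature -> tuple of levels.
    structure_ : :class:`TANStructure`.
    class_prior_ : ndarray, P(class).
    cpts_ : dict feature -> ndarray; root: (n_classes, n_levels), others:
        (n_classes, n_parent_levels, n_levels).
    cmi_ : dict frozenset({f, g}) -> CMI in bits (the learned edge weights).
    """

    def __init__(self, alpha: float = 1.0, levels: dict | None = None, root: str | None = None,
                 class_variable: str = "osa"):
        self.alpha = alpha
        self.levels = levels
        self.root = root
        self.class_variable = class_variable

    # -- input handling ------------------------------------------------

    def _coerce_X(self, X) -> tuple[pd.DataFrame, list[str]]:
        if isinstance(X, pd.DataFrame):
            df = X.copy()
        elif len(X) > 0 and isinstance(next(iter(X)), EncodedRecord):
            df = pd.DataFrame([r.as_dict() for r in X], columns=list(MODEL_VARIABLES))
        else:
            arr = np.asarray(X, dtype=object)
            if arr.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            df = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
        df = df.where(pd.notna(df), None)
        df = df.replace({"": None})
        return df, [str(c) for c in df.columns]

    def _encode_codes(self, df: pd.DataFrame) -> np.ndarray:
        """Integer level codes, -1 for missing; unseen levels raise."""
        n = len(df)
        codes = np.full((n, len(self.feature_names_in_)), _MISSING, dtype=np.int64)
        for j, f in enumerate(self.feature_names_in_):
            idx = {lvl: k for k, lvl in enumerate(self.levels_[f])}
            col = df[f].to_numpy(dtype=object)
            for i, v in enumerate(col):
                if v is None:
                    continue
                try:
                    codes[i, j] = idx[v]
                except KeyError:
                    raise ValueError(f"unknown level {v!r} for feature {f!r} (row {i})") from None
        return codes

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        df, names = self._coerce_X(X)
        if len(df) == 0:
            raise ValueError("cannot fit on an empty cohort")
        y = np.asarray(list(y), dtype=object)
        if len(y) != len(df):
            raise ValueError("X and y length mismatch")
        if any(v is None for v in y):
            raise ValueError("class labels must be fully observed")
        self.classes_ = np.array(sorted(set(y.tolist()), key=repr), dtype=object)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 observed class levels")
        self.feature_names_in_ = names

        # declared or inferred levels
        if self.levels is not None:
            self.levels_ = {f: tuple(self.levels[f]) for f in names}
        elif set(names) == set(MODEL_VARIABLES):
            self.levels_ = {f: tuple(VARIABLE_LEVELS[f]) for f in names}
        else:
            self.levels_ = {}
            dropped = []
            for f in names:
                observed = sorted({v for v in df[f] if v is not None}, key=repr)
                if not observed:
                    dropped.append(f)
                else:
                    self.levels_[f] = tuple(observed)
            if dropped:
                warnings.warn(f"features never observed, excluded from the model: {dropped}")
                names = [f for f in names if f not in dropped]
                df = df[names]
                if not names:
                    raise ValueError("no observed features remain")
                self.feature_names_in_ = names

        codes = self._encode_codes(df)
        class_idx = {c: i for i, c in enumerate(self.classes_)}
        yc = np.array([class_idx[v] for v in y], dtype=np.int64)
        n_classes = len(self.classes_)

        # pairwise class-conditional mutual information (available-case counts)
        self.cmi_ = {}
        weights: dict[tuple[str, str], float] = {}
        order = sorted(range(len(names)), key=lambda j: names[j])
        for a_pos in range(len(order)):
            for b_pos in range(a_pos + 1, len(order)):
                ja, jb = order[a_pos], order[b_pos]
                fa, fb = names[ja], names[jb]
                mask = (codes[:, ja] != _MISSING) & (codes[:, jb] != _MISSING)
                ka, kb = len(self.levels_[fa]), len(self.levels_[fb])
                counts = np.zeros((ka, kb, n_classes))
                np.add.at(counts, (codes[mask, ja], codes[mask, jb], yc[mask]), 1.0)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    w = conditional_mutual_information(counts, self.alpha)
                self.cmi_[frozenset((fa, fb))] = w
                weights[(fa, fb)] = w

        sorted_names = sorted(names)
        root = self.root if self.root is not None else sorted_names[0]
        if root not in names:
            raise ValueError(f"root {root!r} not among features")
        edges = _maximum_spanning_tree(sorted_names, weights, root)
        self.structure_ = TANStructure(
            class_variable=self.class_variable,
            feature_order=tuple(names),
            tree_edges=edges,
            root_feature=root,
        )
        self.structure_.validate()
        self._fit_cpts(codes, yc)
        self.n_features_in_ = len(names)
        self.metadata_ = {"training_n": int(len(df)), "version": SCHEMA_VERSION}
        return self

    def _fit_cpts(self, codes: np.ndarray, yc: np.ndarray) -> None:
        names = self.feature_names_in_
        col = {f: names.index(f) for f in names}
        n_classes = len(self.classes_)
        alpha = float(self.alpha)

        cc = np.bincount(yc, minlength=n_classes).astype(float)
        prior = cc + alpha
        self.class_prior_ = prior / prior.sum()

        parent = {c: p for p, c in self.structure_.tree_edges}
        self.cpts_ = {}
        for f in names:
            jf = col[f]
            kf = len(self.levels_[f])
            if f == self.structure_.root_feature:
                mask = codes[:, jf] != _MISSING
                counts = np.zeros((n_classes, kf))
                np.add.at(counts, (yc[mask], codes[mask, jf]), 1.0)
            else:
                p = parent[f]
                jp = col[p]
                kp = len(self.levels_[p])
                mask = (codes[:, jf] != _MISSING) & (codes[:, jp] != _MISSING)
                counts = np.zeros((n_classes, kp, kf))
                np.add.at(counts, (yc[mask], codes[mask, jp], codes[mask, jf]), 1.0)
            sm = counts + alpha
            denom = sm.sum(axis=-1, keepdims=True)
            # alpha=0 with an unseen parent configuration: fall back to uniform
            uniform = np.full_like(sm, 1.0 / kf)
            with np.errstate(invalid="ignore", divide="ignore"):
                cpt = np.where(denom > 0, sm / np.where(denom > 0, denom, 1.0), uniform)
            self.cpts_[f] = cpt

    # -- inference -------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "cpts_"):
            raise ValueError("TANClassifier instance is not fitted yet")

    def _log_joint_complete(self, codes: np.ndarray) -> np.ndarray:
        """log P(class, all features) for fully observed code rows -> (n, n_classes)."""
        names = self.feature_names_in_
        col = {f: names.index(f) for f in names}
        parent = {c: p for p, c in self.structure_.tree_edges}
        n = codes.shape[0]
        n_classes = len(self.classes_)
        with np.errstate(divide="ignore"):
            out = np.tile(np.log(self.class_prior_), (n, 1))
            for f in names:
                cpt = np.log(np.clip(self.cpts_[f], 1e-300, None))
                if f == self.structure_.root_feature:
                    out += cpt[:, codes[:, col[f]]].T
                else:
                    out += cpt[:, codes[:, col[parent[f]]], codes[:, col[f]]].T
        return out

    def _log_class_scores(self, codes: np.ndarray) -> np.ndarray:
        """log P(class, observed evidence), missing features marginalized exactly."""
        n = codes.shape[0]
        n_classes = len(self.classes_)
        out = np.empty((n, n_classes))
        complete = ~(codes == _MISSING).any(axis=1)
        if complete.any():
            out[complete] = self._log_joint_complete(codes[complete])
        for i in np.nonzero(~complete)[0]:
            row = codes[i]
            missing = np.nonzero(row == _MISSING)[0]
            level_counts = [len(self.levels_[self.feature_names_in_[j]]) for j in missing]
            completions = np.array(list(itertools.product(*[range(k) for k in level_counts])),
                                   dtype=np.int64)
            expanded = np.tile(row, (len(completions), 1))
            expanded[:, missing] = completions
            out[i] = logsumexp(self._log_joint_complete(expanded), axis=0)
        return out

    def predict_proba(self, X) -> np.ndarray:
        """P(class | observed evidence), rows summing to 1; columns follow ``classes_``."""
        self._check_fitted()
        df, names = self._coerce_X(X)
        if list(names) != list(self.feature_names_in_):
            if set(names) >= set(self.feature_names_in_):
                df = df[list(self.feature_names_in_)]
            else:
                raise ValueError("X columns do not match the fitted features")
        codes = self._encode_codes(df)
        log_scores = self._log_class_scores(codes)
        log_norm = logsumexp(log_scores, axis=1, keepdims=True)
        return np.exp(log_scores - log_norm)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def predict_osa_probability(self, X, positive_class=True) -> np.ndarray:
        """P(positive class | evidence) as a flat array (the screening score)."""
        proba = self.predict_proba(X)
        where = np.nonzero([c == positive_class for c in self.classes_])[0]
        if len(where) != 1:
            raise ValueError(f"positive class {positive_class!r} not among classes {self.classes_}")
        return proba[:, where[0]]

    # -- persistence -----------------------------------------------------

    @staticmethod
    def _class_to_json(c):
        if isinstance(c, (bool, np.bool_)):
            return {"type": "bool", "value": bool(c)}
        if isinstance(c, (int, np.integer)):
            return {"type": "int", "value": int(c)}
        return {"type": "str", "value": str(c)}

    @staticmethod
    def _class_from_json(obj):
        return {"bool": bool, "int": int, "str": str}[obj["type"]](obj["value"])

    def to_dict(self) -> dict:
        self._check_fitted()
        parent = {c: p for p, c in self.structure_.tree_edges}
        cpts_json: dict[str, dict[str, list[float]]] = {}
        for f in self.feature_names_in_:
            table: dict[str, list[float]] = {}
            cpt = self.cpts_[f]
            if f == self.structure_.root_feature:
                for ci, c in enumerate(self.classes_):
                    table[f"{self.class_variable}={c}"] = [float(v) for v in cpt[ci]]
            else:
                p = parent[f]
                for ci, c in enumerate(self.classes_):
                    for pi, pv in enumerate(self.levels_[p]):
                        table[f"{self.class_variable}={c}|{p}={pv}"] = [float(v) for v in cpt[ci, pi]]
            cpts_json[f] = table
        return {
            "schema_version": SCHEMA_VERSION,
            "class_variable": self.class_variable,
            "classes": [self._class_to_json(c) for c in self.classes_],
            "levels": {f: list(self.levels_[f]) for f in self.feature_names_in_},
            "feature_order": list(self.feature_names_in_),
            "root": self.structure_.root_feature,
            "edges": [[p, c] for p, c in self.structure_.tree_edges],
            "class_prior": [float(v) for v in self.class_prior_],
            "cpts": cpts_json,
            "alpha": float(self.alpha),
            "metadata": getattr(self, "metadata_", {}),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TANClassifier":
        if data.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {data.get('schema_version')!r}; expected {SCHEMA_VERSION}"
            )
        model = cls(alpha=data["alpha"], root=data["root"], class_variable=data["class_variable"])
        model.classes_ = np.array([cls._class_from_json(c) for c in data["classes"]], dtype=object)
        model.feature_names_in_ = list(data["feature_order"])
        model.levels_ = {f: tuple(lv) for f, lv in data["levels"].items()}
        model.structure_ = TANStructure(
            class_variable=data["class_variable"],
            feature_order=tuple(model.feature_names_in_),
            tree_edges=tuple((p, c) for p, c in data["edges"]),
            root_feature=data["root"],
        )
        model.structure_.validate()
        model.class_prior_ = np.array(data["class_prior"], dtype=float)
        parent = {c: p for p, c in model.structure_.tree_edges}
        model.cpts_ = {}
        for f in model.feature_names_in_:
            kf = len(model.levels_[f])
            table = data["cpts"][f]
            if f == data["root"]:
                cpt = np.empty((len(model.classes_), kf))
                for ci, c in enumerate(model.classes_):
                    cpt[ci] = table[f"{model.class_variable}={c}"]
            else:
                p = parent[f]
                kp = len(model.levels_[p])
                cpt = np.empty((len(model.classes_), kp, kf))
                for ci, c in enumerate(model.classes_):
                    for pi, pv in enumerate(model.levels_[p]):
                        cpt[ci, pi] = table[f"{model.class_variable}={c}|{p}={pv}"]
            model.cpts_[f] = cpt
        model.n_features_in_ = len(model.feature_names_in_)
        model.metadata_ = data.get("metadata", {})
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "TANClassifier":
        with open(path, encoding="utf-8") as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: not a valid model file ({exc})") from None
        if not isinstance(data, dict) or "schema_version" not in data:
            raise ValueError(f"{path}: missing schema_version; not a model file")
        return cls.from_dict(data)

    # -- sampling (ancestral) ---------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
        """Exact ancestral sampling from the TAN joint: class, then features along the tree."""
        self._check_fitted()
        n_classes = len(self.classes_)
        yc = _sample_categorical(np.tile(self.class_prior_, (n, 1)), rng)
        names = self.feature_names_in_
        parent = {c: p for p, c in self.structure_.tree_edges}
        # topological order: root first, then edge order (oriented away from root)
        topo = [self.structure_.root_feature] + [c for _p, c in self.structure_.tree_edges]
        codes = {}
        for f in topo:
            if f == self.structure_.root_feature:
                probs = self.cpts_[f][yc]
            else:
                probs = self.cpts_[f][yc, codes[parent[f]]]
            codes[f] = _sample_categorical(probs, rng)
        data = {f: np.array(self.levels_[f], dtype=object)[codes[f]] for f in names}
        return pd.DataFrame(data, columns=list(names)), self.classes_[yc]


def _sample_categorical(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise categorical draw from an (n, k) probability matrix."""
    cum = np.cumsum(probs, axis=1)
    cum /= cum[:, -1:]
    u = rng.random(probs.shape[0])
    return (u[:, None] > cum).sum(axis=1)


# ---------------------------------------------------------------------------
# thin functional wrappers


def learn_structure(X, y, alpha: float = 1.0, levels: dict | None = None,
                    root: str | None = None) -> TANStructure:
    """Maximum-CMI spanning tree over the features; deterministic tie-breaks."""
    return TANClassifier(alpha=alpha, levels=levels, root=root).fit(X, y).structure_


def fit_parameters(X, y, alpha: float = 1.0, levels: dict | None = None,
                   root: str | None = None) -> TANClassifier:
    """Fit structure and CPTs; returns the fitted classifier (the model)."""
    return TANClassifier(alpha=alpha, levels=levels, root=root).fit(X, y)


def predict_probability(model: TANClassifier, evidence: EncodedRecord, positive_class=True) -> float:
    """P(positive class | one evidence record), marginalizing missing features."""
    return float(model.predict_osa_probability([evidence], positive_class=positive_class)[0])


def save_model(model: TANClassifier, path) -> None:
    model.save(path)


def load_model(path) -> TANClassifier:
    return TANClassifier.load(path)
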