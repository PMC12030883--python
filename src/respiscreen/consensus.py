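"""Consensus classification with a prediction-disagreement applicability domain.

Several base classifiers — each a (featurization scheme, learner) pair — are
trained on the same molecules and combined by averaging their predicted
probabilities of the Active class.  For molecule *j* with per-model outputs
y_jm and consensus mean ȳ_j, the disagreement statistic

    CONS-STD_j = sqrt( (1/N) Σ_m (ȳ_j − y_jm)² )

gates the applicability domain: molecules whose CONS-STD exceeds a threshold
calibrated on cross-validated training disagreement (95th percentile by
default) are called Inconclusive rather than Active/Inactive.

Descriptor packages tied to commercial platforms are not reproduced; the
consensus machinery is generic over the featurizer registry below (circular
fingerprints, MACCS keys, physicochemical descriptors via RDKit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .chemistry import MoleculeRecord

# ---------------------------------------------------------------------------
# featurization

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)

_PHYSCHEM_DESCRIPTORS = (
    ("MolWt", Descriptors.MolWt),
    ("MolLogP", Descriptors.MolLogP),
    ("TPSA", Descriptors.TPSA),
    ("NumHDonors", Descriptors.NumHDonors),
    ("NumHAcceptors", Descriptors.NumHAcceptors),
    ("NumRotatableBonds", Descriptors.NumRotatableBonds),
    ("RingCount", Descriptors.RingCount),
    ("NumAromaticRings", Descriptors.NumAromaticRings),
    ("FractionCSP3", Descriptors.FractionCSP3),
    ("HeavyAtomCount", Descriptors.HeavyAtomCount),
    ("NHOHCount", Descriptors.NHOHCount),
    ("NOCount", Descriptors.NOCount),
    ("LabuteASA", Descriptors.LabuteASA),
    ("MolMR", Descriptors.MolMR),
)


def _morgan_row(mol: Chem.Mol) -> np.ndarray:
    return _MORGAN.GetFingerprintAsNumPy(mol).astype(np.float64)


def _maccs_row(mol: Chem.Mol) -> np.ndarray:
    return np.array(MACCSkeys.GenMACCSKeys(mol), dtype=np.float64)


def _physchem_row(mol: Chem.Mol) -> np.ndarray:
    vals = np.array([fn(mol) for _, fn in _PHYSCHEM_DESCRIPTORS], dtype=np.float64)
    return np.nan_to_num(vals, nan=0.0, posinf=0.0, neginf=0.0)


FEATURIZERS = {
    "morgan": _morgan_row,
    "maccs": _maccs_row,
    "physchem": _physchem_row,
}


def _as_mol(x) -> Chem.Mol | None:
    if isinstance(x, Chem.Mol):
        return x
    if isinstance(x, MoleculeRecord):
        return x.structure
    return Chem.MolFromSmiles(x)


def featurize(molecules: Iterable, scheme: str) -> pd.DataFrame:
    """Feature matrix for one scheme; rows keyed by record id where known.

    Deterministic per scheme: the same structure maps to the same row
    regardless of dataset context.  Unparsable molecules raise; use
    :meth:`ConsensusClassifier.predict_detail` for fault-tolerant prediction.
    """
    if scheme not in FEATURIZERS:
        raise ValueError(f"unknown featurization scheme {scheme!r}; "
                         f"available: {sorted(FEATURIZERS)}")
    fn = FEATURIZERS[scheme]
    rows, index = [], []
    for i, x in enumerate(molecules):
        mol = _as_mol(x)
        if mol is None:
            raise ValueError(f"unparsable molecule at position {i}")
        rows.append(fn(mol))
        index.append(x.record_id if isinstance(x, MoleculeRecord) else i)
    if scheme == "physchem":
        columns = [name for name, _ in _PHYSCHEM_DESCRIPTORS]
    else:
        columns = [f"{scheme}_{j}" for j in range(len(rows[0]) if rows else 0)]
    return pd.DataFrame(rows, index=index, columns=columns)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    """Confusion-matrix statistics; undefined ratios stay None, never 0."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None

    @property
    def acc(self) -> float | None:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else None

    @property
    def sen(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def spe(self) -> float | None:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else None

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "acc": self.acc, "sen": self.sen, "spe": self.spe, "auc": self.auc}


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValueError("confusion counts must be non-negative with a positive sum")
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (ties count 1/2): P(random active outranks random inactive)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC is undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def metrics_from_scores(
    y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.5,
) -> MetricsReport:
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    report = compute_metrics(tp, fp, tn, fn)
    try:
        report.auc = compute_auc(scores, y_true)
    except ValueError:
        report.auc = None
    return report


def consensus_std(values: Sequence[float]) -> float:
    """Disagreement of per-model outputs: sqrt of mean squared deviation."""
    arr = np.asarray(values, dtype=float)
    return float(np.sqrt(np.mean((arr.mean() - arr) ** 2)))


# ---------------------------------------------------------------------------
# splitting and cross-validation


@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    fraction_train: float
    seed: int


def split_train_test(
    ids: Sequence, y: Sequence[int] | None = None,
    fraction_train: float = 0.8, seed: int = 0,
) -> SplitPlan:
    """Random stratified train/test partition with |train| = round(f*N)."""
    ids = list(ids)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 records to split")
    n_train = round(fraction_train * n)
    stratify = None
    if y is not None:
        y = np.asarray(y)
        if len(np.unique(y)) > 1:
            stratify = y
        else:
            warnings.warn("single-class input; splitting without stratification")
    train_ids, test_ids = train_test_split(
        ids, train_size=n_train, random_state=seed, stratify=stratify)
    return SplitPlan(train_ids=list(train_ids), test_ids=list(test_ids),
                     fraction_train=fraction_train, seed=seed)


def cross_validate(
    estimator, X: Sequence, y: Sequence[int], k: int = 5, seed: int = 0,
) -> tuple[np.ndarray, MetricsReport]:
    """Stratified k-fold out-of-fold probabilities plus their metrics.

    Every molecule receives exactly one out-of-fold prediction.
    """
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError("k cannot exceed the number of records")
    X = list(X)
    oof = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        model = clone(estimator)
        model.fit([X[i] for i in train_idx], y[train_idx])
        proba = model.predict_proba([X[i] for i in test_idx])[:, 1]
        oof[test_idx] = proba
    return oof, metrics_from_scores(y, oof)


# ---------------------------------------------------------------------------
# consensus estimator


def default_members(n_members: int = 5, random_state: int | None = None):
    """Featurizer x learner menu for the consensus (4-5 members typical)."""
    rs = random_state
    menu = [
        ("morgan", RandomForestClassifier(n_estimators=200, random_state=rs)),
        ("physchem", RandomForestClassifier(n_estimators=200, random_state=rs)),
        ("morgan", LogisticRegression(max_iter=2000, C=1.0)),
        ("physchem", HistGradientBoostingClassifier(random_state=rs)),
        ("maccs", make_pipeline(StandardScaler(),
                                LogisticRegression(max_iter=2000))),
    ]
    return menu[:n_members]


@dataclass
class ConsensusPrediction:
    """Per-molecule consensus output with the applicability-domain verdict."""

    record_id: object
    per_model: tuple | None
    y_mean: float | None
    cons_std: float | None
    in_domain: bool
    call: str  # Active / Inactive / Inconclusive
    reason: str = ""


class ConsensusClassifier(BaseEstimator, ClassifierMixin):
    """Probability-averaging consensus of featurizer x learner base models.

    Parameters
    ----------
    members : list of (scheme, estimator) pairs, optional
        Base models; defaults to :func:`default_members` with ``n_members``.
    n_members : int
        Size of the default menu when ``members`` is None.
    decision_threshold : float
        In-domain molecules with consensus mean >= threshold are Active.
    ad_quantile : float
        Quantile of cross-validated training CONS-STD used as the
        applicability-domain cutoff.
    cv : int
        Folds for the internal stratified cross-validation.
    greedy_selection : bool
        If True, build the consensus by greedy forward selection of members
        on out-of-fold AUC (a member is kept only if it improves it);
        disabled by default, in which case all members are included.

    Attributes (post-fit)
    ---------------------
    base_models_ : list of (scheme, fitted estimator)
    ad_threshold_ : float
    cv_predictions_ : per-member out-of-fold probabilities, shape (n, N)
    train_metrics_ : MetricsReport of the consensus out-of-fold predictions
    """

    def __init__(self, members=None, n_members: int = 5,
                 decision_threshold: float = 0.5, ad_quantile: float = 0.95,
                 cv: int = 5, greedy_selection: bool = False,
                 random_state: int | None = None):
        self.members = members
        self.n_members = n_members
        self.decision_threshold = decision_threshold
        self.ad_quantile = ad_quantile
        self.cv = cv
        self.greedy_selection = greedy_selection
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _member_specs(self):
        if self.members is not None:
            specs = list(self.members)
        else:
            specs = default_members(self.n_members, self.random_state)
        if len(specs) < 2:
            raise ValueError("a consensus needs at least 2 base models")
        return specs

    def _features(self, mols, scheme_cache):
        out = {}
        for scheme in {s for s, _ in self._member_specs()}:
            if scheme not in scheme_cache:
                scheme_cache[scheme] = np.vstack(
                    [FEATURIZERS[scheme](m) for m in mols])
            out[scheme] = scheme_cache[scheme]
        return out

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels are degenerate (single class)")
        mols = [_as_mol(x) for x in X]
        if any(m is None for m in mols):
            raise ValueError("unparsable molecule in training input")
        self.classes_ = np.array([0, 1])
        specs = self._member_specs()
        cache: dict[str, np.ndarray] = {}
        feats = self._features(mols, cache)

        # per-member out-of-fold probabilities (AD calibration + selection)
        skf = StratifiedKFold(n_splits=self.cv, shuffle=True,
                              random_state=self.random_state)
        folds = list(skf.split(np.zeros(len(y)), y))
        oof = np.full((len(y), len(specs)), np.nan)
        for m, (scheme, est) in enumerate(specs):
            Xf = feats[scheme]
            for train_idx, test_idx in folds:
                model = clone(est)
                model.fit(Xf[train_idx], y[train_idx])
                oof[test_idx, m] = model.predict_proba(Xf[test_idx])[:, 1]

        if self.greedy_selection:
            chosen = self._greedy_select(oof, y)
        else:
            chosen = list(range(len(specs)))
        self.member_indices_ = chosen
        oof = oof[:, chosen]
        specs = [specs[m] for m in chosen]

        self.base_models_ = []
        for scheme, est in specs:
            model = clone(est)
            model.fit(feats[scheme], y)
            self.base_models_.append((scheme, model))

        self.cv_predictions_ = oof
        cv_std = np.array([consensus_std(row) for row in oof])
        self.ad_threshold_ = float(np.quantile(cv_std, self.ad_quantile))
        self.train_metrics_ = metrics_from_scores(y, oof.mean(axis=1),
                                                  self.decision_threshold)
        return self

    def _greedy_select(self, oof: np.ndarray, y: np.ndarray) -> list[int]:
        """Forward selection on out-of-fold AUC, best-first seeding."""
        aucs = [compute_auc(oof[:, m], y) for m in range(oof.shape[1])]
        order = sorted(range(len(aucs)), key=lambda m: -aucs[m])
        chosen = [order[0]]
        best = aucs[order[0]]
        for m in order[1:]:
            trial = compute_auc(oof[:, chosen + [m]].mean(axis=1), y)
            if trial > best:
                chosen.append(m)
                best = trial
        if len(chosen) < 2:  # a consensus of one is no consensus
            chosen = order[:2]
        return sorted(chosen)

    def _per_model_proba(self, mols) -> np.ndarray:
        check_is_fitted(self, "base_models_")
        cols = []
        cache: dict[str, np.ndarray] = {}
        for scheme, model in self.base_models_:
            if scheme not in cache:
                cache[scheme] = np.vstack([FEATURIZERS[scheme](m) for m in mols])
            cols.append(model.predict_proba(cache[scheme])[:, 1])
        return np.column_stack(cols)

    def predict_proba(self, X):
        mols = [_as_mol(x) for x in X]
        if any(m is None for m in mols):
            raise ValueError("unparsable molecule; use predict_detail for "
                             "fault-tolerant screening")
        p = self._per_model_proba(mols).mean(axis=1)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return (p >= self.decision_threshold).astype(int)

    def predict_detail(self, X, ids: Sequence | None = None) -> list[ConsensusPrediction]:
        """Full consensus output: per-model values, mean, CONS-STD, AD call.

        Unparsable/unfeaturizable molecules are returned Inconclusive with a
        reason instead of raising.
        """
        check_is_fitted(self, "base_models_")
        out: list[ConsensusPrediction] = []
        for i, x in enumerate(X):
            rid = ids[i] if ids is not None else (
                x.record_id if isinstance(x, MoleculeRecord) else i)
            mol = _as_mol(x)
            if mol is None:
                out.append(ConsensusPrediction(
                    record_id=rid, per_model=None, y_mean=None, cons_std=None,
                    in_domain=False, call="Inconclusive",
                    reason="featurization failure"))
                continue
            per_model = self._per_model_proba([mol])[0]
            y_mean = float(per_model.mean())
            std = consensus_std(per_model)
            in_domain = std <= self.ad_threshold_
            if not in_domain:
                call = "Inconclusive"
            else:
                call = "Active" if y_mean >= self.decision_threshold else "Inactive"
            out.append(ConsensusPrediction(
                record_id=rid, per_model=tuple(float(v) for v in per_model),
                y_mean=y_mean, cons_std=std, in_domain=in_domain, call=call))
        return out


def save_model(model: ConsensusClassifier, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> ConsensusClassifier:
    return joblib.load(path)
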