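"""Group-wise random-forest models, selection and weighted ensembles.

Feature groups are the modelling unit. For each mutation class the final
predictor combines an energy-based score and a nonenergy-based score:

* protein-DNA mutations (MPD):
  ``energy = alpha * ETOR_pred + (1 - alpha) * EPI_pred`` (alpha = 0.4 for
  the HCT generalized-Born tag);
* protein-RNA mutations (MPR): ``energy = EWC_pred``;
* both: ``score = beta * energy + (1 - beta) * nonenergy`` with beta = 0.6
  (MPD) and 0.5 (MPR).

Evaluation is leave-one-complex-out (LOCOV): each fold holds out every
mutation of one complex. Feature-group subsets are chosen by sequential
backward selection on the pooled out-of-fold criterion (Pearson r for
regression, AUC for classification), and the ensemble weights by an
exhaustive 11-point grid over [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from .structure_io import MutationRecord

log = logging.getLogger(__name__)

DEFAULT_SEED = 2021
DEFAULT_N_TREES = 500
HOTSPOT_THRESHOLD = 1.0  # kcal/mol
WEIGHT_GRID = tuple(round(0.1 * i, 1) for i in range(11))


class ModelingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Mutations with complete feature blocks and regression labels."""

    records: list[MutationRecord]
    features: dict[str, np.ndarray]  # group -> (n, dim)
    ddg: np.ndarray  # kcal/mol
    hotspot_threshold: float = HOTSPOT_THRESHOLD

    def __post_init__(self) -> None:
        self.ddg = np.asarray(self.ddg, dtype=float)
        n = len(self.records)
        if len(self.ddg) != n:
            raise ModelingError("ddg length mismatch")
        for g, X in self.features.items():
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or len(X) != n:
                raise ModelingError(f"group {g}: expected ({n}, dim) matrix")
            self.features[g] = X

    def __len__(self) -> int:
        return len(self.records)

    @property
    def groups(self) -> tuple:
        return tuple(self.features)

    @property
    def complex_ids(self) -> np.ndarray:
        return np.array([r.complex_id for r in self.records])

    @property
    def hotspot(self) -> np.ndarray:
        """Class flags: affinity significantly decreased (ddG >= threshold)."""
        return label_hotspot(self.ddg, self.hotspot_threshold)

    def labels(self, task: str) -> np.ndarray:
        if task == "regression":
            return self.ddg
        if task == "classification":
            return self.hotspot.astype(int)
        raise ModelingError(f"unknown task {task!r}")

    def matrix(self, groups: Sequence[str]) -> np.ndarray:
        groups = list(groups)
        if not groups:
            raise ModelingError("empty group set")
        missing = [g for g in groups if g not in self.features]
        if missing:
            raise ModelingError(f"groups not in dataset: {missing}")
        return np.hstack([self.features[g] for g in groups])

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(
            records=[self.records[i] for i in idx],
            features={g: X[idx] for g, X in self.features.items()},
            ddg=self.ddg[idx],
            hotspot_threshold=self.hotspot_threshold,
        )

    def with_groups(self, extra: dict[str, np.ndarray]) -> "Dataset":
        feats = dict(self.features)
        feats.update(extra)
        return Dataset(self.records, feats, self.ddg, self.hotspot_threshold)


def label_hotspot(ddg, threshold: float = HOTSPOT_THRESHOLD):
    """Flag mutations significantly decreasing affinity (ddG >= threshold)."""
    return np.asarray(ddg, dtype=float) >= threshold


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def locov_splits(ds: Dataset) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Leave-one-complex-out folds ``(complex_id, train_idx, test_idx)``,
    ordered by complex id."""
    cids = ds.complex_ids
    unique = sorted(set(cids))
    if len(unique) < 2:
        raise ModelingError("LOCOV needs mutations from at least two complexes")
    folds = []
    for cid in unique:
        test = np.flatnonzero(cids == cid)
        train = np.flatnonzero(cids != cid)
        folds.append((cid, train, test))
    return folds


# ---------------------------------------------------------------------------
# group models
# ---------------------------------------------------------------------------

@dataclass
class GroupModel:
    """A random forest fitted on the concatenated vectors of a group set."""

    groups: tuple
    task: str
    seed: int
    model: object
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ModelingError(
                f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"model expects {self.n_features}"
            )
        if self.task == "regression":
            return self.model.predict(X)
        if len(self.model.classes_) == 1:  # degenerate single-class training fold
            return np.full(len(X), float(self.model.classes_[0]))
        return self.model.predict_proba(X)[:, 1]


def _make_forest(task: str, seed: int, n_estimators: int):
    if task == "regression":
        return RandomForestRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    return RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)


def fit_group_model(
    ds: Dataset,
    groups: Sequence[str],
    task: str = "regression",
    seed: int = DEFAULT_SEED,
    n_estimators: int = DEFAULT_N_TREES,
) -> GroupModel:
    """Fit a forest on the given feature groups; deterministic given seed."""
    X = ds.matrix(groups)
    y = ds.labels(task)
    model = _make_forest(task, seed, n_estimators)
    model.fit(X, y)
    return GroupModel(
        groups=tuple(groups), task=task, seed=seed, model=model, n_features=X.shape[1]
    )


def locov_predictions(
    ds: Dataset,
    groups: Sequence[str],
    task: str = "regression",
    seed: int = DEFAULT_SEED,
    n_estimators: int = DEFAULT_N_TREES,
) -> np.ndarray:
    """Pooled out-of-fold predictions, aligned with the dataset order."""
    X = ds.matrix(groups)
    y = ds.labels(task)
    out = np.empty(len(ds))
    for _, train, test in locov_splits(ds):
        model = _make_forest(task, seed, n_estimators)
        ytr = y[train]
        if task == "classification" and len(np.unique(ytr)) == 1:
            out[test] = float(ytr[0])
            continue
        model.fit(X[train], ytr)
        if task == "regression":
            out[test] = model.predict(X[test])
        else:
            out[test] = model.predict_proba(X[test])[:, 1]
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pcc(pred, obs) -> float:
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if len(pred) < 2:
        raise ModelingError("PCC needs at least two observations")
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(pearsonr(pred, obs)[0])


def rmse(pred, obs) -> float:
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def regression_metrics(pred, obs) -> dict[str, float]:
    return {"PCC": pcc(pred, obs), "RMSE": rmse(pred, obs)}


def classification_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """MCC at the given score threshold plus rank-based AUC.

    The AUC is the Mann-Whitney statistic (ties get half credit); both
    classes must be present.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ModelingError("classification metrics need both classes")
    return {
        "MCC": float(matthews_corrcoef(labels, (scores >= threshold).astype(int))),
        "AUC": float(roc_auc_score(labels, scores)),
    }


def metrics(pred, labels, task: str) -> dict[str, float]:
    if task == "regression":
        return regression_metrics(pred, labels)
    if task == "classification":
        return classification_metrics(pred, labels)
    raise ModelingError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# sequential backward selection
# ---------------------------------------------------------------------------

@dataclass
class SBSResult:
    selected: tuple
    trace: list  # per accepted round: {"removed", "groups", "score"}


def sbs_select(
    ds: Dataset,
    candidates: Sequence[str],
    task: str = "regression",
    seed: int = DEFAULT_SEED,
    n_estimators: int = DEFAULT_N_TREES,
) -> SBSResult:
    """Sequential backward selection over feature groups.

    Starts from all candidates; each round drops the group whose removal
    most improves the pooled LOCOV criterion (PCC for regression, AUC for
    classification); halts when no removal improves it. Removal ties break
    toward the lexicographically smallest group name.
    """
    current = sorted(candidates)
    if not current:
        raise ModelingError("at least one candidate group required")

    def criterion(groups) -> float:
        preds = locov_predictions(ds, groups, task, seed, n_estimators)
        y = ds.labels(task)
        if task == "regression":
            return pcc(preds, y)
        return classification_metrics(preds, y)["AUC"]

    score = criterion(current)
    trace = [{"removed": None, "groups": tuple(current), "score": score}]
    while len(current) > 1:
        best_g, best_s = None, -np.inf
        for g in current:  # already sorted: first strict improvement wins ties
            s = criterion([x for x in current if x != g])
            if s > best_s:
                best_g, best_s = g, s
        if best_s > score:
            current = [x for x in current if x != best_g]
            score = best_s
            trace.append({"removed": best_g, "groups": tuple(current), "score": score})
        else:
            break
    return SBSResult(selected=tuple(current), trace=trace)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSpec:
    """Final-model recipe: selected groups, weights and GB-model tag."""

    mutation_class: str  # MPD | MPR
    alpha: Optional[float]
    beta: float
    gb_model_tag: str
    energy_groups: tuple
    nonenergy_groups: tuple

    def __post_init__(self) -> None:
        if self.mutation_class not in ("MPD", "MPR"):
            raise ModelingError("mutation_class must be MPD or MPR")
        if self.mutation_class == "MPD":
            if self.alpha is None or not 0.0 <= self.alpha <= 1.0:
                raise ModelingError("MPD requires alpha in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ModelingError("beta must lie in [0, 1]")

    @classmethod
    def for_mpd(cls, **overrides) -> "EnsembleSpec":
        base = dict(
            mutation_class="MPD",
            alpha=0.4,
            beta=0.6,
            gb_model_tag="HCT",
            energy_groups=("ETOR", "EPI"),
            nonenergy_groups=("dASA", "NHB", "CFAA", "CFNA", "IR-CFAA"),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def for_mpr(cls, **overrides) -> "EnsembleSpec":
        base = dict(
            mutation_class="MPR",
            alpha=None,
            beta=0.5,
            gb_model_tag="OBC1",
            energy_groups=("EWC",),
            nonenergy_groups=("bRSA", "uRSA", "dASA", "IR-dASA", "NHB", "ENDES", "JSD"),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def for_class(cls, mutation_class: str, **overrides) -> "EnsembleSpec":
        if mutation_class == "MPD":
            return cls.for_mpd(**overrides)
        if mutation_class == "MPR":
            return cls.for_mpr(**overrides)
        raise ModelingError(f"unknown mutation class {mutation_class!r}")


def energy_score(
    spec: EnsembleSpec,
    etor_pred: Optional[np.ndarray] = None,
    epi_pred: Optional[np.ndarray] = None,
    ewc_pred: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Energy-model score: the alpha-weighted ETOR/EPI combination for MPD,
    the EWC prediction unchanged for MPR."""
    if spec.mutation_class == "MPD":
        if etor_pred is None or epi_pred is None:
            raise ModelingError("MPD energy score requires ETOR and EPI predictions")
        etor_pred = np.asarray(etor_pred, float)
        epi_pred = np.asarray(epi_pred, float)
        if etor_pred.shape != epi_pred.shape:
            raise ModelingError("misaligned ETOR/EPI predictions")
        return spec.alpha * etor_pred + (1.0 - spec.alpha) * epi_pred
    if ewc_pred is None:
        raise ModelingError("MPR energy score requires EWC predictions")
    return np.asarray(ewc_pred, float)


def pempni_score(
    energy_pred: np.ndarray, nonenergy_pred: np.ndarray, spec: EnsembleSpec
) -> np.ndarray:
    """Final integrative score: beta-weighted energy/nonenergy combination."""
    energy_pred = np.asarray(energy_pred, float)
    nonenergy_pred = np.asarray(nonenergy_pred, float)
    if energy_pred.shape != nonenergy_pred.shape:
        raise ModelingError("misaligned energy/nonenergy predictions")
    return spec.beta * energy_pred + (1.0 - spec.beta) * nonenergy_pred


def grid_search_weight(pred_a, pred_b, labels, metric: str = "pcc") -> float:
    """Best weight w for ``w*a + (1-w)*b`` over the 11-point grid {0.0..1.0}.

    Ties break toward the smaller weight.
    """
    pred_a = np.asarray(pred_a, float)
    pred_b = np.asarray(pred_b, float)
    labels = np.asarray(labels, float)
    if not (pred_a.shape == pred_b.shape == labels.shape) or len(labels) < 3:
        raise ModelingError("aligned vectors with at least three labels required")
    if np.std(labels) == 0:
        raise ModelingError("labels have zero variance")
    best_w, best_s = None, -np.inf
    for w in WEIGHT_GRID:
        combo = w * pred_a + (1.0 - w) * pred_b
        s = pcc(combo, labels) if metric == "pcc" else classification_metrics(combo, labels)["AUC"]
        if s > best_s:  # strict: first (smallest) weight wins ties
            best_w, best_s = w, s
    return float(best_w)


# ---------------------------------------------------------------------------
# evaluation and bundles
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    mutation_class: str
    task: str
    complex_ids: list
    predictions: dict[str, np.ndarray]  # component name -> pooled LOCOV preds
    metrics: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "mutation_class": self.mutation_class,
            "task": self.task,
            "metrics": self.metrics,
        }


def _component_predictions(ds, spec, task, seed, n_estimators):
    preds = {}
    if spec.mutation_class == "MPD":
        preds["ETOR"] = locov_predictions(ds, ("ETOR",), task, seed, n_estimators)
        preds["EPI"] = locov_predictions(ds, ("EPI",), task, seed, n_estimators)
        preds["energy"] = energy_score(spec, etor_pred=preds["ETOR"], epi_pred=preds["EPI"])
    else:
        preds["EWC"] = locov_predictions(ds, ("EWC",), task, seed, n_estimators)
        preds["energy"] = energy_score(spec, ewc_pred=preds["EWC"])
    preds["nonenergy"] = locov_predictions(ds, spec.nonenergy_groups, task, seed, n_estimators)
    preds["pempni"] = pempni_score(preds["energy"], preds["nonenergy"], spec)
    return preds


def run_locov(
    ds: Dataset,
    spec: EnsembleSpec,
    task: str = "regression",
    seed: int = DEFAULT_SEED,
    n_estimators: int = DEFAULT_N_TREES,
) -> EvaluationReport:
    """Leave-one-complex-out evaluation of component models and the ensemble."""
    preds = _component_predictions(ds, spec, task, seed, n_estimators)
    y = ds.labels(task)
    mets = {}
    for name, p in preds.items():
        try:
            mets[name] = metrics(p, y, task)
        except ModelingError as exc:  # e.g. single-class toy data
            log.warning("metrics unavailable for %s: %s", name, exc)
    return EvaluationReport(
        mutation_class=spec.mutation_class,
        task=task,
        complex_ids=list(ds.complex_ids),
        predictions=preds,
        metrics=mets,
    )


def tune_weights(
    ds: Dataset,
    spec: EnsembleSpec,
    seed: int = DEFAULT_SEED,
    n_estimators: int = DEFAULT_N_TREES,
) -> EnsembleSpec:
    """Grid-search alpha (MPD only) then beta on pooled LOCOV predictions.

    The two weights are tuned sequentially: alpha on the two energy
    component predictions first, then beta between the resulting energy
    score and the nonenergy prediction.
    """
    task = "regression"
    y = ds.labels(task)
    if spec.mutation_class == "MPD":
        etor_p = locov_predictions(ds, ("ETOR",), task, seed, n_estimators)
        epi_p = locov_predictions(ds, ("EPI",), task, seed, n_estimators)
        alpha = grid_search_weight(etor_p, epi_p, y)
        spec = EnsembleSpec(
            mutation_class=spec.mutation_class, alpha=alpha, beta=spec.beta,
            gb_model_tag=spec.gb_model_tag, energy_groups=spec.energy_groups,
            nonenergy_groups=spec.nonenergy_groups,
        )
        energy_p = energy_score(spec, etor_pred=etor_p, epi_pred=epi_p)
    else:
        energy_p = locov_predictions(ds, ("EWC",), task, seed, n_estimators)
    nonenergy_p = locov_predictions(ds, spec.nonenergy_groups, task, seed, n_estimators)
    beta = grid_search_weight(energy_p, nonenergy_p, y)
    return EnsembleSpec(
        mutation_class=spec.mutation_class, alpha=spec.alpha, beta=beta,
        gb_model_tag=spec.gb_model_tag, energy_groups=spec.energy_groups,
        nonenergy_groups=spec.nonenergy_groups,
    )


@dataclass
class ModelBundle:
    """Trained final models plus the recipe needed to apply them."""

    spec: EnsembleSpec
    seed: int
    models: dict[str, GroupModel]  # "<task>:<component>" -> model
    group_dims: dict[str, int]
    hotspot_threshold: float = HOTSPOT_THRESHOLD

    def _component_inputs(self, features: dict[str, np.ndarray], task: str):
        comps = {}
        if self.spec.mutation_class == "MPD":
            for comp in ("ETOR", "EPI"):
                comps[comp] = self.models[f"{task}:{comp}"].predict(features[comp])
            energy = energy_score(self.spec, etor_pred=comps["ETOR"], epi_pred=comps["EPI"])
        else:
            comps["EWC"] = self.models[f"{task}:EWC"].predict(features["EWC"])
            energy = energy_score(self.spec, ewc_pred=comps["EWC"])
        ne_model = self.models[f"{task}:nonenergy"]
        X = np.hstack([features[g] for g in ne_model.groups])
        nonenergy = ne_model.predict(X)
        return pempni_score(energy, nonenergy, self.spec)

    def predict(self, features: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """ddG estimate and hotspot probability for new mutations."""
        for g, dim in self.group_dims.items():
            if g in features and features[g].shape[1] != dim:
                raise ModelingError(
                    f"group {g}: feature width {features[g].shape[1]} != bundle manifest {dim}"
                )
        out = {"ddg_pred": self._component_inputs(features, "regression")}
        if "classification:nonenergy" in self.models:
            out["hotspot_prob"] = self._component_inputs(features, "classification")
        return out


def fit_bundle(
    ds: Dataset,
    spec: EnsembleSpec,
    seed: int = DEFAULT_SEED,
    n_estimators: int = DEFAULT_N_TREES,
) -> ModelBundle:
    """Fit the final regression and classification component models."""
    models = {}
    for task in ("regression", "classification"):
        if task == "classification" and len(np.unique(ds.labels(task))) < 2:
            log.warning("single-class labels: skipping classification models")
            continue
        for comp in spec.energy_groups:
            models[f"{task}:{comp}"] = fit_group_model(ds, (comp,), task, seed, n_estimators)
        models[f"{task}:nonenergy"] = fit_group_model(
            ds, spec.nonenergy_groups, task, seed, n_estimators
        )
    dims = {g: X.shape[1] for g, X in ds.features.items()}
    return ModelBundle(spec=spec, seed=seed, models=models, group_dims=dims,
                       hotspot_threshold=ds.hotspot_threshold)


def save_bundle(bundle: ModelBundle, path) -> None:
    joblib.dump(bundle, path, compress=0)


def load_bundle(path) -> ModelBundle:
    bundle = joblib.load(path)
    if not isinstance(bundle, ModelBundle):
        raise ModelingError(f"{path} is not a model bundle")
    return bundle
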