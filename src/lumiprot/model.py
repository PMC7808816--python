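"""Gradient-boosted tree classification of fused sequence features.

The modelling surface follows the model/results convention: a
:class:`BLPClassifier` is built from a feature matrix and labels (or from
a labelled dataset plus an encoder config via
:meth:`BLPClassifier.from_dataset`); its :meth:`~BLPClassifier.fit`
returns a :class:`ModelBundle` results object that carries the fitted
booster, the encoder config and column layout it was trained with, and
supports prediction, persistence and a text summary.

The tuned booster protocol ships as the default parameter set
(280 trees, depth 12, learning rate 0.1, gamma 0; every other parameter
at the library default) together with per-species encoder presets, and
:func:`grid_search_encoding` reproduces the encoder-parameter search:
k-fold cross-validated AUC on folds fixed before the grid loop, argmax
by AUC with ties broken toward the lower-dimensional configuration.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from lumiprot.encoders import (
    DatasetEncoder,
    EncoderConfig,
    feature_names,
    fuse_features,
)
from lumiprot.seqio import LabeledDataset, ProteinSequence

_BUNDLE_FORMAT = 1


@dataclass(frozen=True)
class BoosterParams:
    """XGBoost parameters of the tuned protocol.

    ``class_weight_ratio`` is the negative/positive count ratio used as
    the positive-class weight (``None`` = computed from the training
    labels; balanced data gives 1).  Everything not listed here runs at
    the library default.
    """

    n_estimators: int = 280
    max_depth: int = 12
    learning_rate: float = 0.1
    gamma: float = 0.0
    class_weight_ratio: float | None = None
    seed: int = 0


def default_params() -> BoosterParams:
    """The tuned booster defaults: 280 trees, depth 12, lr 0.1, gamma 0."""
    return BoosterParams()


_PRESETS: dict[str, EncoderConfig] = {
    "general": EncoderConfig(
        enabled=("NV", "CTD", "GGAP", "PSEAAC"), g=3, lambda_=18, omega=0.2,
        species="general",
    ),
    "bacteria": EncoderConfig(
        enabled=("CTD", "GGAP", "PSEAAC"), g=3, lambda_=11, omega=0.1,
        species="bacteria",
    ),
    "eukaryote": EncoderConfig(
        enabled=("CTD", "GGAP"), g=6, lambda_=10, omega=1.0,
        species="eukaryote",
    ),
    "archaea": EncoderConfig(
        enabled=("NV", "CTD", "GGAP"), g=1, lambda_=29, omega=0.2,
        species="archaea",
    ),
}


def species_preset(species: str) -> EncoderConfig:
    """Best-performing encoder combination and parameters per species.

    general: NV+CTD+GGAP+PSEAAC, g=3, lambda=18, omega=0.2;
    bacteria: CTD+GGAP+PSEAAC, g=3, lambda=11, omega=0.1;
    eukaryote: CTD+GGAP, g=6; archaea: NV+CTD+GGAP, g=1.
    """
    try:
        return _PRESETS[species]
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}; expected one of {sorted(_PRESETS)}"
        ) from None


def protocol_grid(species: str = "general") -> dict[str, list]:
    """The encoder-parameter search space of the tuning protocol.

    g runs 1..9 for every species; lambda runs 1..38 (general, bacteria),
    1..42 (eukaryote) or 1..48 (archaea); omega runs 0.1..1.0 in steps
    of 0.1.
    """
    lam_max = {"general": 38, "bacteria": 38, "eukaryote": 42, "archaea": 48}
    if species not in lam_max:
        raise ValueError(f"unknown species {species!r}")
    return {
        "g": list(range(1, 10)),
        "lambda_": list(range(1, lam_max[species] + 1)),
        "omega": [round(0.1 * i, 1) for i in range(1, 11)],
    }


def layout_fingerprint(columns: Sequence[str]) -> str:
    h = hashlib.sha256("\x1f".join(columns).encode())
    return h.hexdigest()[:16]


class BLPClassifier:
    """Boosted-tree model over a fused feature matrix.

    Parameters
    ----------
    features : pandas.DataFrame
        n_samples x n_features, no missing values; column names define
        the layout the fitted model is locked to.
    labels : array-like of {0, 1}
        1 = BLP (positive class).
    params : BoosterParams, optional
        Tuned defaults when omitted.
    config : EncoderConfig, optional
        The encoder config that produced ``features``; stored in the
        bundle so raw sequences can be encoded at prediction time.
    """

    def __init__(self, features: pd.DataFrame, labels, params: BoosterParams | None = None,
                 config: EncoderConfig | None = None):
        X = features if isinstance(features, pd.DataFrame) else pd.DataFrame(features)
        y = np.asarray(labels).astype(int)
        if len(X) != len(y):
            raise ValueError(f"{len(X)} feature rows but {len(y)} labels")
        if X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        classes, counts = np.unique(y, return_counts=True)
        if set(classes) != {0, 1}:
            raise ValueError(f"labels must contain both classes, got {classes.tolist()}")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        self.features = X
        self.labels = y
        self.params = params or default_params()
        self.config = config
        self.n_pos = int(counts[classes == 1][0])
        self.n_neg = int(counts[classes == 0][0])

    @classmethod
    def from_dataset(
        cls,
        data: LabeledDataset,
        config: EncoderConfig,
        params: BoosterParams | None = None,
    ) -> "BLPClassifier":
        X = DatasetEncoder(data.sequences).encode(config)
        return cls(X, data.labels, params=params, config=config)

    def fit(self) -> "ModelBundle":
        """Fit the booster; deterministic for fixed seed and inputs."""
        p = self.params
        ratio = (
            p.class_weight_ratio
            if p.class_weight_ratio is not None
            else self.n_neg / self.n_pos
        )
        clf = xgb.XGBClassifier(
            n_estimators=p.n_estimators,
            max_depth=p.max_depth,
            learning_rate=p.learning_rate,
            gamma=p.gamma,
            scale_pos_weight=ratio,
            random_state=p.seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
        )
        clf.fit(self.features.to_numpy(), self.labels)
        return ModelBundle(
            booster=clf.get_booster(),
            config=self.config,
            columns=list(self.features.columns),
            params=p,
            metadata={
                "n_pos": self.n_pos,
                "n_neg": self.n_neg,
                "class_weight_ratio": ratio,
                "xgboost_version": xgb.__version__,
            },
        )


class ModelBundle:
    """Fitted booster plus the encoder config and column layout it assumes.

    Prediction refuses a feature matrix whose column fingerprint differs
    from the training layout; raw sequences are encoded with the stored
    :class:`EncoderConfig` first.
    """

    def __init__(self, booster: xgb.Booster, config: EncoderConfig | None,
                 columns: list[str], params: BoosterParams, metadata: dict):
        self.booster = booster
        self.config = config
        self.columns = list(columns)
        self.fingerprint = layout_fingerprint(self.columns)
        self.params = params
        self.metadata = dict(metadata)
        self.species = config.species if config is not None else "general"

    # -- prediction ---------------------------------------------------------

    def _matrix(self, data) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            got = layout_fingerprint(list(data.columns))
            if got != self.fingerprint:
                raise ValueError(
                    f"feature layout mismatch: matrix fingerprint {got} != "
                    f"model fingerprint {self.fingerprint}"
                )
            return data.to_numpy()
        if isinstance(data, np.ndarray):
            if data.shape[1] != len(self.columns):
                raise ValueError(
                    f"expected {len(self.columns)} features, got {data.shape[1]}"
                )
            return data
        # assume sequences
        seqs = list(data)
        if not all(isinstance(s, ProteinSequence) for s in seqs):
            raise TypeError(
                "predict expects a DataFrame, an ndarray, or ProteinSequence objects"
            )
        if self.config is None:
            raise ValueError("bundle has no encoder config; pass a feature matrix")
        return np.vstack([fuse_features(s, self.config) for s in seqs]) if seqs else (
            np.empty((0, len(self.columns)))
        )

    def predict_scores(self, data) -> np.ndarray:
        """Per-sample probability of the positive (BLP) class, in [0, 1]."""
        X = self._matrix(data)
        if X.shape[0] == 0:
            return np.empty(0)
        return self.booster.predict(xgb.DMatrix(X, feature_names=None))

    def predict(self, data, threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """(scores, labels); a score exactly at the threshold is positive."""
        scores = self.predict_scores(data)
        return scores, (scores >= threshold).astype(int)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the bundle as one JSON file: metadata + booster model."""
        payload = {
            "format_version": _BUNDLE_FORMAT,
            "xgboost_version": xgb.__version__,
            "config": None if self.config is None else {
                "enabled": list(self.config.enabled),
                "g": self.config.g,
                "lambda_": self.config.lambda_,
                "omega": self.config.omega,
                "species": self.config.species,
            },
            "columns": self.columns,
            "fingerprint": self.fingerprint,
            "params": asdict(self.params),
            "metadata": self.metadata,
            "booster": json.loads(self.booster.save_raw(raw_format="json")),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        try:
            payload = json.loads(Path(path).read_text())
        except (json.JSONDecodeError, OSError) as exc:
            raise ValueError(f"cannot read model bundle {path}: {exc}") from exc
        for key in ("format_version", "columns", "params", "booster", "fingerprint"):
            if key not in payload:
                raise ValueError(f"model bundle {path} is missing section {key!r}")
        if payload["format_version"] != _BUNDLE_FORMAT:
            raise ValueError(
                f"bundle format {payload['format_version']} unsupported "
                f"(this build reads format {_BUNDLE_FORMAT})"
            )
        saved_major = str(payload["xgboost_version"]).split(".")[0]
        if saved_major != xgb.__version__.split(".")[0]:
            raise ValueError(
                f"bundle was written by xgboost {payload['xgboost_version']}, "
                f"running {xgb.__version__}: refusing to load across major versions"
            )
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(payload["booster"]).encode()))
        config = None
        if payload.get("config") is not None:
            c = payload["config"]
            config = EncoderConfig(
                enabled=tuple(c["enabled"]), g=c["g"], lambda_=c["lambda_"],
                omega=c["omega"], species=c["species"],
            )
        bundle = cls(
            booster=booster,
            config=config,
            columns=payload["columns"],
            params=BoosterParams(**payload["params"]),
            metadata=payload.get("metadata", {}),
        )
        if bundle.fingerprint != payload["fingerprint"]:
            raise ValueError("bundle fingerprint does not match its column list")
        return bundle

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "BLP boosted-tree model",
            "=" * 46,
            f"species preset     : {self.species}",
            f"encoder blocks     : {'+'.join(self.config.enabled) if self.config else 'n/a'}",
        ]
        if self.config:
            lines += [
                f"g / lambda / omega : {self.config.g} / {self.config.lambda_} / {self.config.omega}",
            ]
        lines += [
            f"n features         : {len(self.columns)}",
            f"layout fingerprint : {self.fingerprint}",
            f"booster            : {self.params.n_estimators} trees, depth "
            f"{self.params.max_depth}, lr {self.params.learning_rate}, gamma {self.params.gamma}",
            f"class weight ratio : {self.metadata.get('class_weight_ratio', 'n/a')}",
            f"training samples   : {self.metadata.get('n_pos', '?')} BLP / "
            f"{self.metadata.get('n_neg', '?')} non-BLP",
        ]
        return "\n".join(lines)


# -- functional wrappers ----------------------------------------------------

def train(
    features: pd.DataFrame,
    labels,
    params: BoosterParams | None = None,
    config: EncoderConfig | None = None,
) -> ModelBundle:
    """Fit a booster on an encoded feature matrix."""
    return BLPClassifier(features, labels, params=params, config=config).fit()


def predict(bundle: ModelBundle, data, threshold: float = 0.5):
    """Scores and thresholded labels for sequences or a feature matrix."""
    return bundle.predict(data, threshold=threshold)


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    bundle.save(path)


def load_bundle(path: str | Path) -> ModelBundle:
    return ModelBundle.load(path)


# -- encoder-parameter grid search ------------------------------------------

def grid_search_encoding(
    data: LabeledDataset,
    grid: Mapping[str, Sequence] | None = None,
    k: int = 10,
    seed: int = 0,
    base: EncoderConfig | None = None,
    params: BoosterParams | None = None,
) -> tuple[EncoderConfig, pd.DataFrame]:
    """Select encoder parameters by k-fold cross-validated AUC.

    ``grid`` maps any of ``g``, ``lambda_``, ``omega`` to candidate
    values; unlisted parameters stay at the ``base`` config's value
    (default: the species preset for ``data.species``).  Folds are
    stratified, fixed by ``seed`` before the loop, and shared across all
    grid points so the comparison is paired.  Grid points whose lambda
    reaches the shortest sequence length are skipped with a warning.
    Ties in mean AUC break toward smaller lambda, then smaller g, then
    smaller omega.

    Returns the winning config and the per-point report table
    (g, lambda, omega, per-fold AUCs, mean AUC).
    """
    from lumiprot.evaluate import make_folds, roc_auc

    base = base or species_preset(data.species)
    params = params or default_params()
    grid = dict(grid or {"g": protocol_grid(data.species)["g"]})
    unknown = set(grid) - {"g", "lambda_", "omega"}
    if unknown:
        raise ValueError(f"unknown grid axes {sorted(unknown)}")
    axes = {name: list(values) for name, values in grid.items()}
    if any(len(v) == 0 for v in axes.values()):
        raise ValueError("empty grid axis")

    min_len = data.min_length()
    y = np.asarray(data.labels)
    folds = make_folds(y, k, seed)
    encoder = DatasetEncoder(data.sequences)

    names = list(axes)
    points = [dict(zip(names, combo)) for combo in itertools.product(*axes.values())]
    rows = []
    best: tuple | None = None  # (mean_auc, -lambda, -g, -omega) maximised
    best_config: EncoderConfig | None = None
    for point in points:
        config = replace(base, **point)
        if "PSEAAC" in config.enabled and config.lambda_ >= min_len:
            warnings.warn(
                f"skipping grid point {point}: lambda={config.lambda_} must be "
                f"smaller than the shortest sequence length ({min_len})",
                stacklevel=2,
            )
            continue
        X = encoder.encode(config)
        fold_aucs = []
        for train_idx, test_idx in folds:
            bundle = BLPClassifier(
                X.iloc[train_idx], y[train_idx], params=params, config=config
            ).fit()
            scores = bundle.predict_scores(X.iloc[test_idx])
            _, auc = roc_auc(y[test_idx], scores)
            fold_aucs.append(auc)
        mean_auc = float(np.mean(fold_aucs))
        rows.append(
            {"g": config.g, "lambda": config.lambda_, "omega": config.omega,
             **{f"fold{i + 1}_auc": a for i, a in enumerate(fold_aucs)},
             "mean_auc": mean_auc}
        )
        key = (mean_auc, -config.lambda_, -config.g, -config.omega)
        if best is None or key > best:
            best = key
            best_config = config
    if best_config is None:
        raise ValueError("no evaluable grid points (all skipped or grid empty)")
    return best_config, pd.DataFrame(rows)
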