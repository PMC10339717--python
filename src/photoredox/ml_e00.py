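"""Machine-learned 0-0 transition energies from molecular fingerprints.

The predictor mirrors a chromophore-database workflow: each SMILES is
hashed into a 2048-bit Morgan (circular, radius 2) fingerprint, the
targets are 0-0 energies obtained by averaging the absorption and
emission maxima (each converted to eV first), min-max scaled into
[0, 1] on the training split, and regressed by a single-hidden-layer
feed-forward network:

    2048 -> 100 (ReLU) -> dropout 0.5 (training only) -> 1

trained with Adam (learning rate 0.001) for 20 epochs on a mean
absolute error loss, after an 80:20 random train/test split.  One model
is trained per solvent; a model never silently predicts for a solvent
it was not trained on.

The network is implemented directly on NumPy so that a single integer
seed fixes the split, the weight initialization and every dropout mask,
making predictions bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .constants import HC_EV_NM
from .excited_state import E00Estimate, E00Route

logger = logging.getLogger(__name__)

FINGERPRINT_BITS = 2048
FINGERPRINT_RADIUS = 2


@dataclass(frozen=True)
class ChromophoreEntry:
    """One chromophore-database record: structure, solvent and maxima."""

    smiles: str
    solvent: str
    lambda_abs: float  # nm
    lambda_em: float   # nm
    e00: float | None = None  # eV, derived by build_targets only

    def __post_init__(self) -> None:
        if self.lambda_abs <= 0 or self.lambda_em <= 0:
            raise ValueError(
                f"{self.smiles}: wavelengths must be positive"
            )


def build_targets(entries: Iterable[ChromophoreEntry]) -> list[ChromophoreEntry]:
    """Attach the 0-0 target: mean of the converted absorption/emission maxima.

    Each maximum is converted to eV (E = hc/lambda) and the two energies
    averaged.  Records with nonpositive wavelengths are rejected with a
    logged reason rather than silently dropped.
    """
    out: list[ChromophoreEntry] = []
    rejected = 0
    for e in entries:
        try:
            e00 = 0.5 * (HC_EV_NM / e.lambda_abs + HC_EV_NM / e.lambda_em)
        except ZeroDivisionError:
            rejected += 1
            logger.warning("rejected %s: zero wavelength", e.smiles)
            continue
        out.append(replace(e, e00=e00))
    if rejected:
        logger.warning("rejected %d records with invalid wavelengths", rejected)
    return out


_FP_GENERATORS: dict[tuple[int, int], object] = {}


def _fp_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _FP_GENERATORS[key]


class FeaturizationError(ValueError):
    """SMILES could not be parsed into a molecule."""


def featurize(
    smiles: str,
    *,
    radius: int = FINGERPRINT_RADIUS,
    n_bits: int = FINGERPRINT_BITS,
) -> np.ndarray:
    """2048-bit Morgan fingerprint of a SMILES string (uint8 0/1 vector).

    The molecule is canonicalized by the parser, so different spellings
    of the same structure give identical vectors.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    fp = _fp_generator(radius, n_bits).GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def featurize_batch(
    smiles_list: Sequence[str],
    *,
    radius: int = FINGERPRINT_RADIUS,
    n_bits: int = FINGERPRINT_BITS,
) -> tuple[np.ndarray, list[int], list[str]]:
    """Featurize a batch; returns (matrix, kept indices, failed SMILES)."""
    rows, kept, failed = [], [], []
    for i, smi in enumerate(smiles_list):
        try:
            rows.append(featurize(smi, radius=radius, n_bits=n_bits))
            kept.append(i)
        except FeaturizationError:
            failed.append(smi)
    if failed:
        logger.warning("failed to featurize %d SMILES", len(failed))
    X = np.array(rows, dtype=np.float64) if rows else np.empty((0, n_bits))
    return X, kept, failed


# --------------------------------------------------------------------------
# Target scaling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetScaler:
    """Min-max transform to [0, 1], fitted on the training split only.

    Values outside the fitted range are not clamped, so the inverse is
    exact everywhere.
    """

    min_: float
    max_: float

    @classmethod
    def fit(cls, values: Sequence[float]) -> "TargetScaler":
        v = np.asarray(values, dtype=float)
        if v.size < 2 or np.ptp(v) == 0:
            raise ValueError(
                "target scaling needs at least two distinct values"
            )
        return cls(min_=float(v.min()), max_=float(v.max()))

    def scale(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.min_) / (self.max_ - self.min_)

    def unscale(self, scaled) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * (self.max_ - self.min_) + self.min_


def split_dataset(
    entries: Sequence, ratio: float = 0.8, seed: int = 0
) -> tuple[list, list]:
    """Random disjoint, exhaustive train/test split, reproducible by seed."""
    n = len(entries)
    if n < 5:
        raise ValueError(f"need at least 5 entries to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(ratio * n))
    train_idx, test_idx = order[:n_train], order[n_train:]
    return [entries[i] for i in train_idx], [entries[i] for i in test_idx]


# --------------------------------------------------------------------------
# The network
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MLConfig:
    """Architecture and optimizer settings of the E00 regressor."""

    hidden_units: int = 100
    dropout: float = 0.5
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 32
    radius: int = FINGERPRINT_RADIUS
    n_bits: int = FINGERPRINT_BITS


class _MLP:
    """2048 -> hidden (ReLU) -> inverted dropout -> 1, Adam on MAE loss."""

    def __init__(self, cfg: MLConfig, rng: np.random.Generator):
        h = cfg.hidden_units
        # He-uniform initialization for the ReLU layer.
        lim1 = np.sqrt(6.0 / cfg.n_bits)
        lim2 = np.sqrt(6.0 / h)
        self.W1 = rng.uniform(-lim1, lim1, size=(cfg.n_bits, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.uniform(-lim2, lim2, size=(h, 1))
        self.b2 = np.zeros(1)
        self.cfg = cfg
        self._adam_m = [np.zeros_like(p) for p in self._params()]
        self._adam_v = [np.zeros_like(p) for p in self._params()]
        self._adam_t = 0

    def _params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        z1 = X @ self.W1 + self.b1
        h = np.maximum(z1, 0.0)
        mask = None
        if rng is not None and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            mask = (rng.random(h.shape) < keep) / keep
            h = h * mask
        out = h @ self.W2 + self.b2
        return out[:, 0], (X, z1, h, mask)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, rng=None)[0]

    def _adam_step(self, grads):
        cfg = self.cfg
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self._params(), grads, self._adam_m, self._adam_v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._adam_t)
            vhat = v / (1 - b2 ** self._adam_t)
            p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    def train_batch(self, X, y, rng: np.random.Generator) -> float:
        pred, (X_, z1, h, mask) = self.forward(X, rng=rng)
        resid = pred - y
        loss = float(np.abs(resid).mean())
        n = X.shape[0]
        dout = np.sign(resid)[:, None] / n          # d(MAE)/d(out)
        gW2 = h.T @ dout
        gb2 = dout.sum(axis=0)
        dh = dout @ self.W2.T
        if mask is not None:
            dh = dh * mask
        dz1 = dh * (z1 > 0)
        gW1 = X_.T @ dz1
        gb1 = dz1.sum(axis=0)
        self._adam_step([gW1, gb1, gW2, gb2])
        return loss


@dataclass
class E00Model:
    """A trained per-solvent E00 regressor with its scaling and metadata."""

    solvent: str
    config: MLConfig
    scaler: TargetScaler
    net: _MLP
    seed: int
    train_mae: float | None = None  # eV, after inverse scaling
    test_mae: float | None = None   # eV


class SolventMismatchError(ValueError):
    """Model asked to predict for a solvent it was not trained on."""


def _xy(entries: Sequence[ChromophoreEntry], cfg: MLConfig):
    missing = [e.smiles for e in entries if e.e00 is None]
    if missing:
        raise ValueError(
            f"{len(missing)} entries lack targets; run build_targets first"
        )
    X, kept, failed = featurize_batch(
        [e.smiles for e in entries], radius=cfg.radius, n_bits=cfg.n_bits
    )
    y = np.array([entries[i].e00 for i in kept])
    return X, y


def train(
    train_set: Sequence[ChromophoreEntry],
    config: MLConfig = MLConfig(),
    *,
    solvent: str | None = None,
    seed: int = 0,
    test_set: Sequence[ChromophoreEntry] | None = None,
) -> E00Model:
    """Fit the regressor on a featurized, target-scaled training split.

    All randomness (initialization, batch order, dropout masks) derives
    from ``seed``.  Train/test MAE are recorded in eV after inverse
    scaling when the corresponding split is available.
    """
    if not train_set:
        raise ValueError("empty training set")
    if solvent is None:
        solvents = {e.solvent for e in train_set}
        if len(solvents) != 1:
            raise ValueError(
                f"training set spans solvents {sorted(solvents)}; train one "
                "model per solvent"
            )
        solvent = solvents.pop()
    X, y = _xy(train_set, config)
    scaler = TargetScaler.fit(y)
    ys = scaler.scale(y)
    rng = np.random.default_rng(seed)
    net = _MLP(config, rng)
    n = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            net.train_batch(X[idx], ys[idx], rng)
    model = E00Model(solvent=solvent, config=config, scaler=scaler, net=net,
                     seed=seed)
    model.train_mae = float(np.abs(scaler.unscale(net.predict(X)) - y).mean())
    if test_set:
        Xt, yt = _xy(test_set, config)
        model.test_mae = float(
            np.abs(scaler.unscale(net.predict(Xt)) - yt).mean()
        )
    return model


def predict(
    model: E00Model,
    smiles_list: Sequence[str],
    *,
    solvent: str | None = None,
    allow_solvent_mismatch: bool = False,
) -> tuple[list[E00Estimate], list[str]]:
    """Predict E00 (eV) for a batch of SMILES; returns (estimates, failed).

    Unparseable SMILES fail individually and are reported in the second
    element; the batch continues.  Requesting a solvent other than the
    model's raises unless explicitly overridden.
    """
    if solvent is not None and solvent != model.solvent:
        if not allow_solvent_mismatch:
            raise SolventMismatchError(
                f"model trained for {model.solvent!r}, requested {solvent!r}"
            )
        logger.warning(
            "predicting for %r with a model trained on %r", solvent,
            model.solvent,
        )
    cfg = model.config
    X, kept, failed = featurize_batch(
        smiles_list, radius=cfg.radius, n_bits=cfg.n_bits
    )
    values = model.scaler.unscale(model.net.predict(X)) if kept else []
    estimates = [
        E00Estimate(molecule_id=smiles_list[i], solvent=model.solvent,
                    value=float(v), route=E00Route.ML)
        for i, v in zip(kept, values)
    ]
    return estimates, failed


def grid_search(
    entries: Sequence[ChromophoreEntry],
    grids: dict[str, Sequence],
    *,
    split_seed: int = 0,
    train_seed: int = 0,
    ratio: float = 0.8,
) -> tuple[MLConfig, list[dict]]:
    """Exhaustive hyperparameter search minimizing held-out MAE.

    The train/test split is fixed across grid cells so that cells are
    comparable.  Returns the best config and the full report table.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grid must be nonempty in every dimension")
    unknown = set(grids) - set(MLConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown grid dimensions: {sorted(unknown)}")
    train_set, test_set = split_dataset(entries, ratio=ratio, seed=split_seed)
    names = sorted(grids)
    report: list[dict] = []
    best: tuple[float, MLConfig] | None = None
    from itertools import product
    for combo in product(*(grids[n] for n in names)):
        cfg = replace(MLConfig(), **dict(zip(names, combo)))
        model = train(train_set, cfg, seed=train_seed, test_set=test_set)
        row = {**dict(zip(names, combo)), "test_mae": model.test_mae,
               "train_mae": model.train_mae}
        report.append(row)
        if best is None or model.test_mae < best[0]:
            best = (model.test_mae, cfg)
    return best[1], report


# --------------------------------------------------------------------------
# Serialization: npz weights + JSON metadata sidecar
# --------------------------------------------------------------------------

def save_model(model: E00Model, path: str | Path) -> Path:
    """Write the model bundle: ``<path>.npz`` weights, ``<path>.json`` metadata."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), W1=model.net.W1, b1=model.net.b1,
             W2=model.net.W2, b2=model.net.b2)
    meta = {
        "solvent": model.solvent,
        "config": asdict(model.config),
        "scaler": {"min": model.scaler.min_, "max": model.scaler.max_},
        "seed": model.seed,
        "train_mae_eV": model.train_mae,
        "test_mae_eV": model.test_mae,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> E00Model:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = MLConfig(**meta["config"])
    net = _MLP(cfg, np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as z:
        net.W1, net.b1 = z["W1"], z["b1"]
        net.W2, net.b2 = z["W2"], z["b2"]
    return E00Model(
        solvent=meta["solvent"], config=cfg,
        scaler=TargetScaler(min_=meta["scaler"]["min"],
                            max_=meta["scaler"]["max"]),
        net=net, seed=meta["seed"], train_mae=meta["train_mae_eV"],
        test_mae=meta["test_mae_eV"],
    )
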