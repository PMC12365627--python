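"""SKiNET: supervised self-organizing map with a class discriminant index.

A Kohonen self-organizing map (SOM) places neurons on a hexagonal lattice;
each neuron carries a spectral weight vector of length D (the number of
wavenumber variables).  Training gradually pulls the weights toward
presented spectra so that nearby neurons respond to similar spectra.  The
supervised extension appends a nonnegative class-weight vector of length K
to every neuron, updated jointly with the spectral weights using the same
learning rate and neighborhood, with the one-hot training label as the
target.  The best-matching unit (BMU) is always found on the spectral part
alone, so classification of unlabeled spectra is label-free: a new
spectrum's predicted class is the argmax of its BMU's normalized class
weights.

The self-organizing-map discriminant index (SOMDI) extracts, per class k,
the wavenumbers that drive clustering: S_k = sum_i C[i,k] * (W_i - Wbar),
where Wbar is the mean spectral weight over all neurons.  Negative entries
are rectified to zero and the vector is normalized to maximum 1; its peaks
mark the bands contributing most to that class's separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .core import EvspecError, LabeledDataset, WavenumberAxis


@dataclass(frozen=True)
class SOMParams:
    """Training hyperparameters.

    ``steps`` is the total number of single-spectrum presentations; when
    None it is epochs x |training set| (the reference configuration used a
    10 x 10 grid, an initial learning rate of 0.1 and 4 epochs).
    """

    rows: int = 10
    cols: int = 10
    steps: int | None = None
    epochs: int = 4
    eta0: float = 0.1
    sigma0: float | None = None  # default max(rows, cols) / 2
    eta_decay: bool = True
    topology: str = "hexagonal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise EvspecError("grid dimensions must be >= 1")
        if not 0 < self.eta0 <= 1:
            raise EvspecError("eta0 must be in (0, 1]")
        if self.sigma0 is not None and self.sigma0 <= 0:
            raise EvspecError("sigma0 must be positive")
        if self.steps is not None and self.steps < 1:
            raise EvspecError("steps must be >= 1")
        if self.epochs < 1:
            raise EvspecError("epochs must be >= 1")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    @property
    def sigma_start(self) -> float:
        return self.sigma0 if self.sigma0 is not None else max(self.rows, self.cols) / 2.0


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.2
    stratified: bool = True
    seed: int = 0
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise EvspecError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise EvspecError("cv_folds must be >= 2")


def _grid_positions(rows: int, cols: int) -> np.ndarray:
    """Cartesian coordinates of a pointy-top hexagonal lattice.

    Odd rows are shifted by half a cell; row spacing is sqrt(3)/2, so
    lattice distance is Euclidean distance between hexagon centres.
    """
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = c + 0.5 * (r % 2)
    y = r * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel(), y.ravel()])


@dataclass
class SOMModel:
    params: SOMParams
    W: np.ndarray  # (n_neurons, D) spectral weights
    C: np.ndarray  # (n_neurons, K) class weights, entries >= 0
    class_names: list[str]
    trained: bool = False
    axis: WavenumberAxis | None = None

    def __post_init__(self) -> None:
        if self.W.shape[0] != self.params.n_neurons or self.C.shape[0] != self.params.n_neurons:
            raise EvspecError("weight matrices must have one row per neuron")
        if np.any(self.C < 0):
            raise EvspecError("class weights must be nonnegative")

    @property
    def D(self) -> int:
        return self.W.shape[1]

    @property
    def K(self) -> int:
        return self.C.shape[1]

    # --- serialization -------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "params": {
                "rows": self.params.rows, "cols": self.params.cols,
                "steps": self.params.steps, "epochs": self.params.epochs,
                "eta0": self.params.eta0, "sigma0": self.params.sigma0,
                "eta_decay": self.params.eta_decay,
                "topology": self.params.topology, "seed": self.params.seed,
            },
            "W": self.W.tolist(), "C": self.C.tolist(),
            "class_names": self.class_names, "trained": self.trained,
            "axis": None if self.axis is None else
                    {"start": self.axis.start, "stop": self.axis.stop, "step": self.axis.step},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "SOMModel":
        with open(path) as fh:
            obj = json.load(fh)
        axis = WavenumberAxis(**obj["axis"]) if obj["axis"] else None
        return cls(
            SOMParams(**obj["params"]),
            np.asarray(obj["W"], dtype=float),
            np.asarray(obj["C"], dtype=float),
            list(obj["class_names"]),
            trained=bool(obj["trained"]),
            axis=axis,
        )


@dataclass
class SOMDIResult:
    """Per-class discriminant spectra over the wavenumber axis."""

    axis: WavenumberAxis
    vectors: dict[str, np.ndarray]  # rectified, max-normalized
    peaks: dict[str, list[tuple[float, float]]]  # (wavenumber, score), ranked
    degenerate: list[str] = field(default_factory=list)


def init_som(
    params: SOMParams,
    D: int,
    K: int,
    seed: int | None = None,
    data: np.ndarray | None = None,
) -> SOMModel:
    """Initialize weights uniformly in the per-variable data range.

    Without data the spectral weights are uniform in [-1, 1]; class weights
    start uniform at 1/K.
    """
    if D < 1 or K < 1:
        raise EvspecError("D and K must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if data is not None:
        lo, hi = data.min(axis=0), data.max(axis=0)
    else:
        lo, hi = np.full(D, -1.0), np.full(D, 1.0)
    W = rng.uniform(size=(params.n_neurons, D)) * (hi - lo) + lo
    C = np.full((params.n_neurons, K), 1.0 / K)
    return SOMModel(params, W, C, class_names=[f"class{k}" for k in range(K)])


def bmu(model: SOMModel, spectrum: np.ndarray) -> int:
    """Best-matching unit: minimal Euclidean distance on the spectral part.

    Ties break to the lowest neuron index.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.shape != (model.D,):
        raise EvspecError(f"spectrum length {x.size} does not match model D={model.D}")
    d2 = np.einsum("ij,ij->i", model.W - x, model.W - x)
    return int(np.argmin(d2))


def quantization_error(model: SOMModel, X: np.ndarray) -> float:
    """Mean Euclidean distance from each sample to its BMU's weights."""
    X = np.atleast_2d(X)
    d = np.sqrt(((X[:, None, :] - model.W[None, :, :]) ** 2).sum(axis=2))
    return float(d.min(axis=1).mean())


def train_som(
    model: SOMModel,
    X: np.ndarray,
    y: np.ndarray,
    class_names: list[str],
    track_qe: bool = False,
) -> SOMModel | tuple[SOMModel, list[float]]:
    """Train the supervised SOM on spectra X with integer labels y.

    Runs ``steps`` presentations cycling epochs over a seed-shuffled
    training order.  At step t with BMU b and neighborhood
    h_i = exp(-dist(i, b)^2 / (2 sigma(t)^2)):

        W_i += eta(t) * h_i * (x - W_i)
        C_i += eta(t) * h_i * (onehot(y) - C_i)

    eta decays as eta0 * exp(-t / steps) and sigma as
    sigma0 * exp(-t * ln(sigma0) / steps) (held constant when sigma0 <= 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if X.shape[0] == 0:
        raise EvspecError("empty training set")
    if X.shape[1] != model.D:
        raise EvspecError("training spectra length does not match model")
    K = len(class_names)
    if K != model.K:
        raise EvspecError("class count does not match model")

    p = model.params
    n = X.shape[0]
    steps = p.steps if p.steps is not None else p.epochs * n
    sigma0 = p.sigma_start
    pos = _grid_positions(p.rows, p.cols)
    # pairwise squared lattice distances, row b = distances from neuron b
    d2_lattice = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)

    rng = np.random.default_rng(p.seed)
    order = rng.permutation(n)
    onehot = np.eye(K)

    W = model.W.copy()
    C = model.C.copy()
    qe_per_epoch: list[float] = []
    probe = replace(model)  # shallow view for QE tracking

    for t in range(steps):
        x = X[order[t % n]]
        target = onehot[y[order[t % n]]]
        eta = p.eta0 * np.exp(-t / steps) if p.eta_decay else p.eta0
        if sigma0 > 1.0:
            sigma = sigma0 * np.exp(-t * np.log(sigma0) / steps)
        else:
            sigma = sigma0
        d2 = np.einsum("ij,ij->i", W - x, W - x)
        b = int(np.argmin(d2))
        h = np.exp(-d2_lattice[b] / (2.0 * sigma * sigma))
        W += (eta * h)[:, None] * (x - W)
        C += (eta * h)[:, None] * (target - C)
        if track_qe and (t + 1) % n == 0:
            probe.W = W
            qe_per_epoch.append(quantization_error(probe, X))

    out = SOMModel(p, W, np.clip(C, 0.0, None), list(class_names), trained=True,
                   axis=model.axis)
    if track_qe:
        return out, qe_per_epoch
    return out


def classify(model: SOMModel, spectrum: np.ndarray) -> tuple[str, np.ndarray]:
    """Predict class of a spectrum from its BMU's normalized class weights."""
    if not model.trained:
        raise EvspecError("model is not trained")
    b = bmu(model, spectrum)
    c = model.C[b]
    if c.sum() == 0:
        # fall back to the nearest neuron carrying class mass
        x = np.asarray(spectrum, dtype=float)
        d2 = np.einsum("ij,ij->i", model.W - x, model.W - x)
        for i in np.argsort(d2, kind="stable"):
            if model.C[i].sum() > 0:
                c = model.C[i]
                break
        else:
            raise EvspecError("no neuron carries class weight mass")
    score = c / c.sum()
    return model.class_names[int(np.argmax(score))], score


def neuron_modal_class(model: SOMModel, X: np.ndarray, y: np.ndarray) -> list[str]:
    """Modal training-set class per neuron; 'none' if unactivated or tied."""
    if not model.trained:
        raise EvspecError("model is not trained")
    X = np.atleast_2d(X)
    counts = np.zeros((model.params.n_neurons, model.K), dtype=int)
    for xi, yi in zip(X, np.asarray(y, dtype=int)):
        counts[bmu(model, xi), yi] += 1
    out = []
    for row in counts:
        if row.sum() == 0:
            out.append("none")
            continue
        top = row.max()
        if (row == top).sum() > 1:
            out.append("none")
        else:
            out.append(model.class_names[int(np.argmax(row))])
    return out


def somdi(model: SOMModel, top_n: int = 10) -> SOMDIResult:
    """Class discriminant spectra S_k = sum_i C[i,k] (W_i - Wbar).

    Negative entries are rectified to 0 and each non-degenerate vector is
    normalized to maximum 1.  Ranked local maxima give the wavenumbers most
    responsible for the class's clustering.
    """
    if not model.trained:
        raise EvspecError("model is not trained")
    axis = model.axis or WavenumberAxis(0, model.D - 1, 1)
    wn = axis.values
    Wbar = model.W.mean(axis=0)
    vectors: dict[str, np.ndarray] = {}
    peaks: dict[str, list[tuple[float, float]]] = {}
    degenerate: list[str] = []
    for k, name in enumerate(model.class_names):
        s = model.C[:, k] @ (model.W - Wbar)
        s = np.clip(s, 0.0, None)
        m = s.max()
        if m <= 0 or model.C[:, k].sum() == 0:
            degenerate.append(name)
            vectors[name] = np.zeros(model.D)
            peaks[name] = []
            continue
        s = s / m
        # min separation of ~5 grid points keeps noise ripple on one band
        # from occupying several ranked slots
        idx, props = find_peaks(s, height=0.0, distance=5)
        order = np.argsort(props["peak_heights"])[::-1][:top_n]
        peaks[name] = [(float(wn[idx[i]]), float(props["peak_heights"][i])) for i in order]
        vectors[name] = s
    return SOMDIResult(axis, vectors, peaks, degenerate)


# --- splitting, cross-validation, evaluation ---------------------------

def stratified_split(y: np.ndarray, test_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split into train/test index arrays."""
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for k in np.unique(y):
        idx = np.flatnonzero(y == k)
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 1)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """k stratified folds (round-robin within each shuffled class)."""
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y)
    if k > counts[counts > 0].min():
        raise EvspecError(f"{k} folds infeasible: smallest class has {counts[counts > 0].min()} samples")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _fit_eval(X_tr, y_tr, X_te, y_te, params: SOMParams, class_names: list[str]) -> tuple[SOMModel, float, np.ndarray]:
    model = init_som(params, X_tr.shape[1], len(class_names), data=X_tr)
    model.class_names = list(class_names)
    model = train_som(model, X_tr, y_tr, class_names)
    pred = np.array([classify(model, x)[0] for x in X_te])
    truth = np.array([class_names[i] for i in y_te])
    return model, float(np.mean(pred == truth)), pred


def cross_validate(
    dataset: LabeledDataset,
    param_grid: list[SOMParams],
    split: SplitSpec | None = None,
) -> tuple[SOMParams, list[dict]]:
    """Stratified k-fold mean accuracy per parameter combination.

    Best = argmax accuracy; ties resolve to the smaller grid, then fewer
    training steps.
    """
    split = split or SplitSpec()
    X, y = dataset.X, dataset.y
    folds = stratified_folds(y, split.cv_folds, split.seed)
    table = []
    for params in param_grid:
        accs = []
        for f in range(len(folds)):
            te = folds[f]
            tr = np.concatenate([folds[j] for j in range(len(folds)) if j != f])
            _, acc, _ = _fit_eval(X[tr], y[tr], X[te], y[te], params, dataset.class_names)
            accs.append(acc)
        table.append({"params": params, "cv_accuracy": float(np.mean(accs)),
                      "fold_accuracies": accs})
    def sort_key(row):
        p = row["params"]
        steps = p.steps if p.steps is not None else p.epochs
        return (-row["cv_accuracy"], p.n_neurons, steps)
    best = sorted(table, key=sort_key)[0]["params"]
    return best, table


def train_test_evaluate(
    dataset: LabeledDataset,
    params: SOMParams | None = None,
    split: SplitSpec | None = None,
) -> dict:
    """Hold-out evaluation: stratified 80:20 split, train, classify.

    Returns the trained model, per-class one-vs-rest confusion counts,
    overall accuracy, and the held-out scores/labels for ROC analysis.
    """
    params = params or SOMParams()
    split = split or SplitSpec()
    X, y = dataset.X, dataset.y
    names = dataset.class_names
    tr, te = stratified_split(y, split.test_fraction, split.seed)
    for k in range(len(names)):
        if not np.any(y[tr] == k):
            raise EvspecError(f"class {names[k]!r} absent from training split")
    model = init_som(params, X.shape[1], len(names), data=X[tr])
    model.class_names = list(names)
    model.axis = dataset.axis
    model = train_som(model, X[tr], y[tr], names)

    preds, scores = [], []
    for x in X[te]:
        lab, sc = classify(model, x)
        preds.append(lab)
        scores.append(sc)
    preds = np.array(preds)
    truth = np.array([names[i] for i in y[te]])
    confusion = {}
    for k, name in enumerate(names):
        tp = int(np.sum((preds == name) & (truth == name)))
        fp = int(np.sum((preds == name) & (truth != name)))
        fn = int(np.sum((preds != name) & (truth == name)))
        tn = int(np.sum((preds != name) & (truth != name)))
        confusion[name] = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
    return {
        "model": model,
        "accuracy": float(np.mean(preds == truth)),
        "confusion": confusion,
        "test_scores": np.vstack(scores),
        "test_labels": truth,
        "predictions": preds,
        "train_idx": tr,
        "test_idx": te,
    }
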