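"""K-fold cross-validation protocol, accuracy aggregation and run manifests.

Folds are drawn over pooled windows (all trials mixed) with a seeded shuffle;
an optional ``group_by`` keeps all windows of a trial or subject in the same
fold for users who want the stricter leakage-free protocol. Accuracy is
window-level top-1 in percent; the summary row uses the arithmetic mean and the
population (divide-by-n) standard deviation.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.model_selection import GroupKFold, KFold

from .nn import EmotionNet, NetworkSpec, TrainedModel, predict, train


@dataclass
class FoldResult:
    fold_id: int  # 1-based
    accuracy: float  # percent
    n_train: int
    n_test: int


@dataclass
class CVReport:
    folds: list[FoldResult] = field(default_factory=list)
    task: str = ""
    config_digest: str = ""

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std(self) -> float:
        """Population (divide-by-n) standard deviation of the fold accuracies."""
        return float(self.accuracies.std(ddof=0))

    def to_dataframe(self):
        import pandas as pd

        rows = [(f"Fold {f.fold_id}", f.accuracy) for f in self.folds]
        rows += [("Mean", self.mean), ("Standard Deviation", self.std)]
        return pd.DataFrame(rows, columns=["Fold ID", f"Accuracy (%) [{self.task}]"])

    def __str__(self) -> str:
        lines = [f"Fold {f.fold_id:2d}  {f.accuracy:6.2f}" for f in self.folds]
        lines.append(f"Mean    {self.mean:6.2f}")
        lines.append(f"Std     {self.std:6.2f}")
        return "\n".join(lines)


def aggregate_report(accuracies) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation of fold accuracies."""
    acc = np.asarray(list(accuracies), dtype=np.float64)
    if acc.size == 0:
        raise ValueError("need at least one fold accuracy")
    return float(acc.mean()), float(acc.std(ddof=0))


def kfold_split(n_samples: int, k: int = 10, seed: int = 0, groups=None) -> list[np.ndarray]:
    """Disjoint test-index arrays covering 0..n-1; sizes differ by at most one.

    ``groups`` (per-sample trial/subject ids) switches to grouped folds that
    never split a group across train and test.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_samples < k:
        raise ValueError(f"cannot split {n_samples} windows into {k} folds")
    idx = np.arange(n_samples)
    if groups is not None:
        splitter = GroupKFold(n_splits=k)
        return [test for _, test in splitter.split(idx, groups=groups)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(idx)]


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))


def config_digest(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: NetworkSpec,
    k: int = 10,
    seed: int = 0,
    epochs: int | None = None,
    task: str = "",
    groups=None,
    verbose: bool = False,
) -> CVReport:
    """Train a fresh network per fold and report held-out window accuracy (%)."""
    X = np.asarray(X)
    y = np.asarray(y)
    folds = kfold_split(X.shape[0], k=k, seed=seed, groups=groups)
    all_idx = np.arange(X.shape[0])
    report = CVReport(
        task=task,
        config_digest=config_digest({"spec": spec, "k": k, "seed": seed, "epochs": epochs}),
    )
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        fseed = _fold_seed(seed, i)
        net = EmotionNet(spec, seed=fseed)
        train(net, X[train_idx], y[train_idx], spec, seed=fseed, epochs=epochs)
        _, labels = predict(net, X[test_idx])
        acc = 100.0 * float((labels == y[test_idx]).mean())
        report.folds.append(
            FoldResult(fold_id=i + 1, accuracy=acc, n_train=len(train_idx), n_test=len(test_idx))
        )
        if verbose:
            print(f"fold {i + 1}/{k}: {acc:.2f}%")
    return report


def write_manifest(path, config: dict) -> None:
    """Record config, seeds and versions so a run can be repeated bit-compatibly."""
    manifest = {
        "config": config,
        "digest": config_digest(config),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "platform": platform.platform(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False, default_flow_style=False)


def save_model(model_dir, model: TrainedModel) -> None:
    """Model directory: parameters (.npz), spec (.yaml) and history (.csv)."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    net = model.net
    arrays = dict(net.parameters())
    for name, bn in list(net.bns.items()) + ([("fc", net.bn_fc)] if net.bn_fc is not None else []):
        arrays[f"bn{name}.running_mean"] = bn.running_mean
        arrays[f"bn{name}.running_var"] = bn.running_var
    np.savez_compressed(model_dir / "params.npz", **{k.replace("/", "_"): v for k, v in arrays.items()})
    from dataclasses import asdict

    with open(model_dir / "spec.yaml", "w") as fh:
        yaml.safe_dump({"spec": asdict(model.spec), "rng_seed": model.rng_seed}, fh, sort_keys=False)
    import pandas as pd

    pd.DataFrame(model.history).to_csv(model_dir / "history.csv", index=False)


def load_model(model_dir) -> TrainedModel:
    model_dir = Path(model_dir)
    with open(model_dir / "spec.yaml") as fh:
        payload = yaml.safe_load(fh)
    spec_dict = payload["spec"]
    for key in ("input_shape", "conv_filters", "kernel", "pool", "dropout_at", "batchnorm_at"):
        spec_dict[key] = tuple(spec_dict[key])
    spec_dict["residual_links"] = tuple(tuple(l) for l in spec_dict["residual_links"])
    spec = NetworkSpec(**spec_dict)
    net = EmotionNet(spec, seed=payload.get("rng_seed", 0))
    params = net.parameters()
    with np.load(model_dir / "params.npz") as z:
        for k, arr in params.items():
            arr[...] = z[k]
        for name, bn in list(net.bns.items()) + ([("fc", net.bn_fc)] if net.bn_fc is not None else []):
            bn.running_mean[...] = z[f"bn{name}.running_mean"]
            bn.running_var[...] = z[f"bn{name}.running_var"]
    import pandas as pd

    history_path = model_dir / "history.csv"
    history = pd.read_csv(history_path).to_dict("records") if history_path.exists() else []
    return TrainedModel(net=net, spec=spec, history=history, rng_seed=payload.get("rng_seed", 0))
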