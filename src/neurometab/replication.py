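"""Train/validation replication of the voxel-metabolite integration.

The cohort is split 67/33 stratified by diagnosis (round-half-up per
stratum, reproducing the reference split of 40/57 training and 20/28
validation cases/controls). Integration is re-run on the training subjects
with the fixed full-data cutoff; every training edge's Pearson correlation
is then recomputed on the validation subjects, per-metabolite averages are
taken, and ordinary least squares summarizes agreement (slope, intercept,
r, R^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError, InputError
from .network import build_network, compute_association_matrix


@dataclass
class SplitPlan:
    train_ids: list[str]
    valid_ids: list[str]
    counts: dict[str, int] = field(default_factory=dict)
    seed: int = 0


@dataclass
class FitResult:
    slope: float
    intercept: float
    r: float
    r2: float
    n: int


@dataclass
class ReplicationReport:
    pairs: pd.DataFrame                # voxel, metabolite, r_train, r_valid
    metabolite_averages: pd.DataFrame  # metabolite, mean r_train/valid, n_voxels
    fit_pairs: FitResult
    fit_averages: FitResult
    cutoff: float
    alpha: float


def stratified_split(
    meta: pd.DataFrame, train_frac: float = 0.67, seed: int = 0
) -> SplitPlan:
    """Random diagnosis-stratified split; per-stratum training size is
    round-half-up(train_frac * stratum size)."""
    if not (0.0 < train_frac < 1.0):
        raise ConfigurationError("train_frac must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    train, valid = [], []
    counts: dict[str, int] = {}
    for group, sub in meta.groupby("diagnosis", sort=True):
        ids = np.array(sub.index)
        if ids.size == 0:
            raise DegenerateInputError(f"stratum {group!r} is empty")
        n_train = int(np.floor(train_frac * ids.size + 0.5))
        perm = rng.permutation(ids)
        train.extend(perm[:n_train])
        valid.extend(perm[n_train:])
        counts[f"train_{group}"] = n_train
        counts[f"valid_{group}"] = ids.size - n_train
    return SplitPlan(train_ids=sorted(train), valid_ids=sorted(valid),
                     counts=counts, seed=seed)


def fit_r2(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Ordinary least squares of y on x with R^2 = 1 - SSE/SST."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("need >= 3 aligned points")
    if np.all(x == x[0]):
        raise DegenerateInputError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        n=int(x.size),
    )


def _pair_correlations(
    X: np.ndarray, M: np.ndarray, vi: np.ndarray, mi: np.ndarray
) -> np.ndarray:
    """Pearson r for specific (voxel, metabolite) column pairs."""
    n = X.shape[0]
    Zx = (X - X.mean(0)) / np.where(X.std(0, ddof=1) == 0, 1.0, X.std(0, ddof=1))
    Zm = (M - M.mean(0)) / np.where(M.std(0, ddof=1) == 0, 1.0, M.std(0, ddof=1))
    return np.einsum("nk,nk->k", Zx[:, vi], Zm[:, mi]) / (n - 1)


def replicate_network(
    X: np.ndarray,
    M: np.ndarray,
    subjects: list[str],
    split: SplitPlan,
    cutoff: float,
    alpha: float = 0.05,
    voxel_ids: list[str] | None = None,
    metabolite_ids: list[str] | None = None,
) -> ReplicationReport:
    """Edges found on training subjects, re-measured on validation subjects.

    The full-data voxel set and cutoff are reused (no re-selection); any
    metabolite with no training edge is simply absent from the report.
    """
    if len(split.valid_ids) < 4:
        raise InputError("validation set must contain >= 4 subjects")
    pos = {s: i for i, s in enumerate(subjects)}
    tr = np.array([pos[s] for s in split.train_ids])
    va = np.array([pos[s] for s in split.valid_ids])

    assoc = compute_association_matrix(
        X[tr], M[tr], mode="pearson",
        voxel_ids=voxel_ids, metabolite_ids=metabolite_ids,
    )
    net = build_network(assoc, cutoff=cutoff, alpha=alpha)
    vmap = {v: i for i, v in enumerate(assoc.voxel_ids)}
    mmap = {m: j for j, m in enumerate(assoc.metabolite_ids)}
    vi = np.array([vmap[v] for v in net.edges["voxel"]])
    mi = np.array([mmap[m] for m in net.edges["metabolite"]])
    r_valid = _pair_correlations(X[va], M[va], vi, mi)

    pairs = pd.DataFrame(
        {
            "voxel": net.edges["voxel"].to_numpy(),
            "metabolite": net.edges["metabolite"].to_numpy(),
            "r_train": net.edges["r"].to_numpy(),
            "r_valid": r_valid,
        }
    )
    averages = (
        pairs.groupby("metabolite")
        .agg(
            mean_r_train=("r_train", "mean"),
            mean_r_valid=("r_valid", "mean"),
            n_voxels=("voxel", "count"),
        )
        .reset_index()
    )
    def _fit_or_nan(x: np.ndarray, y: np.ndarray) -> FitResult:
        try:
            return fit_r2(x, y)
        except DegenerateInputError:
            return FitResult(np.nan, np.nan, np.nan, np.nan, int(x.size))

    fit_pairs = _fit_or_nan(pairs["r_train"].to_numpy(), pairs["r_valid"].to_numpy())
    fit_avg = _fit_or_nan(
        averages["mean_r_train"].to_numpy(), averages["mean_r_valid"].to_numpy()
    )
    return ReplicationReport(
        pairs=pairs,
        metabolite_averages=averages,
        fit_pairs=fit_pairs,
        fit_averages=fit_avg,
        cutoff=cutoff,
        alpha=alpha,
    )
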