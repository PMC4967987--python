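"""Per-slice TP/FP scoring, consensus-mask thresholding and parameter sweeps.

The success measure is voxel-wise and per slice: a true positive is a
nodule voxel labeled nodule, a false positive a voxel labeled nodule that
belongs to another element.  Sweeping an algorithm's parameter grid and
recording (TP%, FP%) per combination traces the tradeoff curve used to
compare algorithms — an ROC-like picture without requiring a full
ground-truth classification of every voxel.

FP normalization: ``fp_pct`` defaults to ``100 * |predicted \\ truth| /
|predicted|`` (the complement of precision).  The alternative denominator
``|domain \\ truth|`` is available via ``fp_denominator='domain'`` and the
choice is recorded in every :class:`EvalRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .algorithms import ALGORITHMS, InitSpec, select_nodule_cluster
from .core import ClusterParams, ImageVolume, ParameterError

__all__ = [
    "NoduleMask",
    "EvalRecord",
    "consensus_filter",
    "tp_fp_rates",
    "parameter_sweep",
    "tradeoff_table",
    "tradeoff_plot",
]

CONSENSUS_MAX = 1000.0


@dataclass
class NoduleMask:
    """Per-voxel nodule scores aligned to an :class:`ImageVolume`.

    ``semantics='binary'`` holds {0, 1}; ``'consensus'`` holds radiologist
    agreement scores in [0, 1000] (1000 = unanimous nodule).
    """

    grid: np.ndarray
    semantics: Literal["binary", "consensus"] = "binary"

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim == 2:
            g = g[np.newaxis]
        if self.semantics == "binary":
            self.grid = g.astype(bool)
        elif self.semantics == "consensus":
            g = g.astype(np.float64)
            if g.min() < 0 or g.max() > CONSENSUS_MAX:
                raise ParameterError("consensus scores must lie in [0, 1000]")
            self.grid = g
        else:
            raise ParameterError(f"unknown mask semantics {self.semantics!r}")

    @property
    def shape(self):
        return self.grid.shape


def consensus_filter(mask: NoduleMask, threshold: float) -> NoduleMask:
    """Binary mask of voxels whose consensus score is >= ``threshold``.

    A threshold of 800 keeps only voxels with strong radiologist agreement.
    """
    if mask.semantics != "consensus":
        raise ParameterError(
            "consensus_filter expects a consensus-valued mask; "
            "binary masks need no filtering"
        )
    if not (0 <= threshold <= CONSENSUS_MAX):
        raise ParameterError(f"threshold must lie in [0, 1000], got {threshold}")
    return NoduleMask(grid=mask.grid >= threshold, semantics="binary")


@dataclass
class EvalRecord:
    """TP/FP score for one slice under one algorithm-parameter combination."""

    slice_index: int
    algorithm: str
    params: dict = field(default_factory=dict)
    tp_count: int = 0
    fp_count: int = 0
    fn_count: int = 0
    tp_pct: float | None = None
    fp_pct: float | None = None
    fp_denominator: str = "predicted"
    domain: str = "full"
    failed: bool = False
    error: str = ""

    def to_row(self) -> dict:
        row = asdict(self)
        row["params"] = ";".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return row


def _as_bool(a) -> np.ndarray:
    g = a.grid if isinstance(a, NoduleMask) else np.asarray(a)
    if g.ndim == 2:
        g = g[np.newaxis]
    return g.astype(bool)


def tp_fp_rates(
    predicted,
    truth,
    domain=None,
    fp_denominator: Literal["predicted", "domain"] = "predicted",
    slice_index: int = 0,
    algorithm: str = "",
    params: dict | None = None,
) -> EvalRecord:
    """Voxel-wise TP/FP counts and percentages for one predicted/truth pair.

    ``tp_pct = 100 * |predicted ∩ truth| / |truth|`` (None when the truth
    is empty — undefined, not zero).  When a ``domain`` mask is given the
    evaluation is restricted to it.
    """
    pred = _as_bool(predicted)
    tru = _as_bool(truth)
    if pred.shape != tru.shape:
        raise ParameterError(f"shape mismatch: predicted {pred.shape} vs truth {tru.shape}")
    if domain is not None:
        dom = _as_bool(domain)
        if dom.shape != pred.shape:
            raise ParameterError(f"shape mismatch: domain {dom.shape} vs masks {pred.shape}")
        pred = pred & dom
        tru = tru & dom
    else:
        dom = np.ones_like(pred)
    tp = int(np.count_nonzero(pred & tru))
    fp = int(np.count_nonzero(pred & ~tru))
    fn = int(np.count_nonzero(tru & ~pred))
    n_truth = tp + fn
    n_pred = tp + fp
    tp_pct = 100.0 * tp / n_truth if n_truth > 0 else None
    if fp_denominator == "predicted":
        fp_pct = 100.0 * fp / n_pred if n_pred > 0 else None
    elif fp_denominator == "domain":
        n_neg = int(np.count_nonzero(dom & ~tru))
        fp_pct = 100.0 * fp / n_neg if n_neg > 0 else None
    else:
        raise ParameterError(f"fp_denominator must be 'predicted' or 'domain'")
    return EvalRecord(
        slice_index=slice_index,
        algorithm=algorithm,
        params=dict(params or {}),
        tp_count=tp,
        fp_count=fp,
        fn_count=fn,
        tp_pct=tp_pct,
        fp_pct=fp_pct,
        fp_denominator=fp_denominator,
        domain="domain" if domain is not None else "full",
    )


def _params_summary(p: ClusterParams) -> dict:
    d = {
        "c": p.c, "m": p.m, "p": p.p, "q": p.q, "alpha": p.alpha,
        "sigma": p.kernel.sigma, "kernel": p.kernel.family,
        "variance_scale": p.kernel.variance_scale,
        "window": p.neighborhood.size, "window_mode": p.neighborhood.mode,
        "include_center": p.neighborhood.include_center,
        "epsilon": p.epsilon, "max_iter": p.max_iter, "seed": p.seed,
    }
    return d


def parameter_sweep(
    volume: ImageVolume,
    truth: NoduleMask,
    algorithm: str,
    grid: Sequence[ClusterParams],
    init: InitSpec,
    hint: Sequence[float] | None = None,
    fp_denominator: Literal["predicted", "domain"] = "predicted",
    use_lung_domain: bool = True,
) -> list[EvalRecord]:
    """Run one solver over a parameter grid and score every slice.

    Yields one :class:`EvalRecord` per (parameter combination, slice), in
    grid order then slice order.  A solver failure for one combination is
    recorded as a failed record rather than aborting the sweep.
    """
    if algorithm not in ALGORITHMS:
        raise ParameterError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}")
    if len(grid) == 0:
        raise ParameterError("empty parameter grid")
    tru = _as_bool(truth)
    if tru.shape != volume.shape:
        raise ParameterError("truth mask shape must match the volume")
    domain = volume.lung_mask if (use_lung_domain and volume.lung_mask is not None) else None
    records: list[EvalRecord] = []
    for params in grid:
        summary = _params_summary(params)
        try:
            state = ALGORITHMS[algorithm](volume, params, init)
            sel = select_nodule_cluster(state, hint=hint)
            predicted = state.labels() == sel
            for z in range(volume.depth):
                rec = tp_fp_rates(
                    predicted[z][np.newaxis],
                    tru[z][np.newaxis],
                    domain=None if domain is None else domain[z][np.newaxis],
                    fp_denominator=fp_denominator,
                    slice_index=z,
                    algorithm=algorithm,
                    params=summary,
                )
                records.append(rec)
        except Exception as exc:  # noqa: BLE001 - failed combos are data
            for z in range(volume.depth):
                records.append(
                    EvalRecord(
                        slice_index=z, algorithm=algorithm, params=summary,
                        failed=True, error=f"{type(exc).__name__}: {exc}",
                        fp_denominator=fp_denominator,
                        domain="domain" if domain is not None else "full",
                    )
                )
    return records


def tradeoff_table(records: Sequence[EvalRecord]) -> pd.DataFrame:
    """Tabulate sweep records sorted by FP% ascending, then TP% descending.

    The resulting table reads like the TP-vs-FP tradeoff scatter: the rows
    at the top dominate (low noise, high detection).
    """
    if len(records) == 0:
        raise ParameterError("no records to tabulate")
    df = pd.DataFrame([r.to_row() for r in records])
    df = df.sort_values(
        by=["algorithm", "fp_pct", "tp_pct"],
        ascending=[True, True, False],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    return df


def tradeoff_plot(records: Sequence[EvalRecord], path) -> None:
    """Scatter the TP-vs-FP tradeoff (one marker per record) to an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = tradeoff_table(records).dropna(subset=["tp_pct", "fp_pct"])
    fig, ax = plt.subplots(figsize=(5, 4))
    for alg, sub in df.groupby("algorithm"):
        ax.scatter(sub["fp_pct"], sub["tp_pct"], label=alg or "(unnamed)", alpha=0.7)
    ax.set_xlabel("FP %")
    ax.set_ylabel("TP %")
    ax.set_xlim(-2, 102)
    ax.set_ylim(-2, 102)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
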