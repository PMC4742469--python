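"""Ensemble tractography: pool candidate connectomes and re-optimize.

The architecture: generate one candidate connectome per tracking parameter
set (an SPC), pool the candidates into an ensemble candidate (ETC) by plain
concatenation — no deduplication; the non-negative fit resolves redundancy —
and fit the pooled candidate with the fascicle-evaluation model. The sweep
axis is agnostic: curvature bound, algorithm, or amplitude stopping criterion.

An optional preselection step builds the ensemble candidate from the
top-weighted streamlines of each individually fitted SPC, which bounds the
pooled problem size for large sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Connectome, DWIDataset, OrientationField
from .metrics import AccuracyReport, evaluate_on_mask
from .tracking import TrackingParams, clip_to_roi, track

__all__ = [
    "combine",
    "preselect",
    "run_ensemble_pipeline",
    "EnsembleResult",
    "PreselectionPolicy",
    "curvature_sweep",
]

STANDARD_RADII_MM = (0.25, 0.5, 1.0, 2.0, 4.0)


def curvature_sweep(
    radii_mm=STANDARD_RADII_MM,
    n_streamlines: int = 400,
    seed: int = 0,
    algorithm: str = "probabilistic",
    min_length: float = 6.0,
    max_length: float = 60.0,
    **kwargs,
) -> list[TrackingParams]:
    """The standard curvature sweep (one parameter set per minimum radius).

    Defaults are scaled to the bundled phantom: the length bounds bracket the
    phantom's bundle lengths (the U-bundle arc is ~9 mm, the long bundle
    26 mm) the way the full-scale 10-200 mm bounds bracket real fascicles.
    Per-sweep seeds are derived deterministically from ``seed``.
    """
    return [
        TrackingParams(
            algorithm=algorithm,
            min_radius_curvature=float(r),
            n_streamlines=n_streamlines,
            min_length=min_length,
            max_length=max_length,
            seed=(seed * 1000 + i) % (2**31),
            **kwargs,
        )
        for i, r in enumerate(radii_mm)
    ]


def combine(connectomes: list[Connectome], label: str = "ETC") -> Connectome:
    """Concatenate candidate connectomes, preserving per-streamline provenance.

    No deduplication: identical streamlines from different inputs are kept;
    the optimization stage resolves redundancy. Output size is the sum of
    input sizes.
    """
    if not connectomes:
        raise ValueError("combine requires at least one input connectome")
    streamlines: list[np.ndarray] = []
    provenance: list[str] = []
    for c in connectomes:
        streamlines.extend(c.streamlines)
        provenance.extend(c.provenance)
    weights = None
    if all(c.weights is not None for c in connectomes):
        weights = np.concatenate([c.weights for c in connectomes])
    return Connectome(streamlines, provenance, weights=weights, label=label)


@dataclass(frozen=True)
class PreselectionPolicy:
    """Exactly one of top_k (count per input) or top_fraction in (0, 1]."""

    top_k: int | None = None
    top_fraction: float | None = None

    def __post_init__(self) -> None:
        if (self.top_k is None) == (self.top_fraction is None):
            raise ValueError("give exactly one of top_k / top_fraction")
        if self.top_fraction is not None and not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def preselect(
    connectomes: list[Connectome],
    top_k: int | None = None,
    top_fraction: float | None = None,
    label: str = "ETCpre",
) -> Connectome:
    """Pool the top-weighted streamlines of each weighted input connectome.

    From each input, streamlines are sorted by descending weight and the top
    ``k`` (or ``ceil(fraction * n)``) are taken; ties at the cutoff keep the
    earlier-indexed streamline. Results are concatenated via :func:`combine`.
    """
    policy = PreselectionPolicy(top_k, top_fraction)
    picked = []
    for c in connectomes:
        if c.weights is None:
            raise ValueError(f"input connectome {c.label!r} carries no weights")
        n = len(c)
        k = policy.top_k if policy.top_k is not None else int(np.ceil(policy.top_fraction * n))
        if k > n:
            raise ValueError(
                f"top_k={k} exceeds the size ({n}) of input connectome {c.label!r}"
            )
        # stable sort on negated weights: ties keep the lower streamline index
        order = np.argsort(-c.weights, kind="stable")[:k]
        picked.append(c.subset(np.sort(order)))
    return combine(picked, label=label)


@dataclass
class EnsembleResult:
    etc_optimized: Connectome
    etc_report: AccuracyReport
    spc_optimized: dict[str, Connectome]
    spc_reports: dict[str, AccuracyReport]
    etc_candidate_size: int
    spc_candidates: dict[str, Connectome] = field(default_factory=dict)
    weighted_candidates: list[Connectome] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def run_ensemble_pipeline(
    field_: OrientationField,
    repeat1: DWIDataset,
    repeat2: DWIDataset | None,
    parameter_sweep: list[TrackingParams],
    preselection: PreselectionPolicy | None = None,
    clip_roi: np.ndarray | None = None,
    fit_mask: np.ndarray | None = None,
    tolerance: float = 1e-6,
    max_iterations: int = 500,
) -> EnsembleResult:
    """Run the full ensemble pipeline on one dataset.

    For each parameter set: track -> (clip) -> fit -> optimized SPC + report;
    then pool the candidates (or the per-SPC top-weighted streamlines when a
    preselection policy is given), fit the pooled candidate, and report the
    optimized ETC. Every stage is seeded through its TrackingParams.
    """
    if not parameter_sweep:
        raise ValueError("parameter sweep must be non-empty")
    sizes = {p.n_streamlines for p in parameter_sweep}
    if len(sizes) > 1:
        import warnings

        warnings.warn("sweep mixes unequal per-SPC candidate counts; the pooled "
                      "candidate will be dominated by the larger inputs")
    if fit_mask is None:
        fit_mask = repeat1.mask
    candidates: dict[str, Connectome] = {}
    spc_optimized: dict[str, Connectome] = {}
    spc_reports: dict[str, AccuracyReport] = {}
    weighted_candidates: list[Connectome] = []
    manifest: dict = {"stages": []}
    for params in parameter_sweep:
        label = params.label
        try:
            cand = track(field_, params)
            if clip_roi is not None:
                cand = clip_to_roi(cand, clip_roi, field_.grid.voxel_size)
                cand.label = label
            report, opt, handle = evaluate_on_mask(
                cand, repeat1, repeat2, fit_mask,
                tolerance=tolerance, max_iterations=max_iterations, label=label,
            )
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"SPC stage {label!r} failed: {exc}") from exc
        candidates[label] = cand
        spc_optimized[label] = opt
        spc_reports[label] = report
        cand_weighted = Connectome(cand.streamlines, cand.provenance,
                                   weights=handle.fit.weights, label=label)
        weighted_candidates.append(cand_weighted)
        manifest["stages"].append(
            {"label": label, "seed": params.seed, "candidate_size": len(cand),
             "optimized_size": len(opt), "median_r_rmse": report.median_r_rmse}
        )
    if preselection is None:
        etc_candidate = combine(list(candidates.values()), label="ETC")
    else:
        etc_candidate = preselect(
            weighted_candidates,
            top_k=preselection.top_k,
            top_fraction=preselection.top_fraction,
            label="ETCpre",
        )
    try:
        etc_report, etc_opt, _ = evaluate_on_mask(
            etc_candidate, repeat1, repeat2, fit_mask,
            tolerance=tolerance, max_iterations=max_iterations,
            label=etc_candidate.label,
        )
    except Exception as exc:
        raise RuntimeError(f"ETC stage failed: {exc}") from exc
    manifest["stages"].append(
        {"label": etc_candidate.label, "candidate_size": len(etc_candidate),
         "optimized_size": len(etc_opt), "median_r_rmse": etc_report.median_r_rmse}
    )
    return EnsembleResult(
        etc_optimized=etc_opt,
        etc_report=etc_report,
        spc_optimized=spc_optimized,
        spc_reports=spc_reports,
        etc_candidate_size=len(etc_candidate),
        spc_candidates=candidates,
        weighted_candidates=weighted_candidates,
        manifest=manifest,
    )
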