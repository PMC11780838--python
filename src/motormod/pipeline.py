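"""End-to-end study orchestration: the full 27-condition, two-leg analysis.

For every condition and leg, activations are generated (synthetic mode) or
loaded from disk (files mode), motor modules are extracted with the module
number selected at each VAF threshold, and the selected modules are
compared to the reference condition (1.1 m/s, symmetric, 0.1 m width):
Pearson structure similarity after optimal matching, fixed-module NNLS
reconstruction VAF, and per-module activation metrics (peak, CoA, DTW of
the reconstructed patterns against the reference patterns).  Left and
right legs are analyzed independently end-to-end; bilateral similarity is
a separate derived table.

All randomness is derived from the config seed, so re-running a study with
the same config reproduces every table exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparison import (
    bilateral_similarity,
    match_modules,
    reconstruct_with_fixed_modules,
)
from .conditions import LEGS, ConditionSpec, condition_grid, reference_condition
from .extraction import ExtractionResult, VafCurve, nmf_decompose, vaf_curve
from .io import load_activation_file
from .metrics import center_of_activity, dtw_distance, peak_activation
from .muscles import get_muscle_set
from .synthetic import GroundTruth, ModulationGains, make_ground_truth, synthesize_activations

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Configuration of one study run.

    ``data_source`` is "synthetic" (generate activations from the planted
    ground truth) or "files" (load ``<condition label>.csv`` or ``.sto``
    from ``input_dir``).  ``n_max`` defaults to 10 for the full muscle set
    and 8 for the subset.  The primary threshold (largest of
    ``vaf_thresholds``) decides the module number used for the structure
    and recruitment comparisons.
    """

    data_source: str = "synthetic"
    input_dir: str | Path | None = None
    muscle_set: str = "subset_8"
    vaf_thresholds: tuple[float, ...] = (0.90, 0.95)
    n_max: int | None = None
    replicates: int = 20
    seed: int = 0
    noise_sd: float = 0.02
    gains: ModulationGains = field(default_factory=ModulationGains)
    n_modules_true: int | None = None
    legs: tuple[str, ...] = LEGS
    max_iter: int = 2000
    tol: float = 1e-6
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.data_source not in ("synthetic", "files"):
            raise ValueError(
                f"data_source must be 'synthetic' or 'files', got {self.data_source!r}"
            )
        for th in self.vaf_thresholds:
            if not 0.0 < th < 1.0:
                raise ValueError(f"VAF thresholds must be in (0,1), got {th}")
        if self.data_source == "files" and self.input_dir is None:
            raise ValueError("files mode requires input_dir")
        if self.n_max is None:
            self.n_max = 8 if self.muscle_set == "subset_8" else 10

    @property
    def primary_threshold(self) -> float:
        return max(self.vaf_thresholds)

    def to_jsonable(self) -> dict:
        d = {
            "data_source": self.data_source,
            "input_dir": str(self.input_dir) if self.input_dir else None,
            "muscle_set": self.muscle_set,
            "vaf_thresholds": list(self.vaf_thresholds),
            "n_max": self.n_max,
            "replicates": self.replicates,
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "gains": vars(self.gains).copy(),
            "n_modules_true": self.n_modules_true,
            "legs": list(self.legs),
            "max_iter": self.max_iter,
            "tol": self.tol,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SummaryTables:
    """Tidy result tables of a study run (one row per analyzed unit)."""

    module_number: pd.DataFrame
    structure_similarity: pd.DataFrame
    reconstruction_vaf: pd.DataFrame
    activation_metrics: pd.DataFrame
    bilateral: pd.DataFrame
    vaf_curves: dict[str, VafCurve]
    metadata: dict
    errors: list[dict] = field(default_factory=list)
    ground_truth: GroundTruth | None = None

    def write(self, output_dir: str | Path) -> None:
        """Write all tables as CSV plus a JSON run-metadata log."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.module_number.to_csv(out / "module_number.csv", index=False)
        self.structure_similarity.to_csv(
            out / "structure_similarity.csv", index=False
        )
        self.reconstruction_vaf.to_csv(out / "reconstruction_vaf.csv", index=False)
        self.activation_metrics.to_csv(out / "activation_metrics.csv", index=False)
        self.bilateral.to_csv(out / "bilateral_similarity.csv", index=False)
        curves = {
            key: {"n": c.n.tolist(), "vaf": c.vaf_at_n.tolist()}
            for key, c in self.vaf_curves.items()
        }
        meta = dict(self.metadata)
        meta["errors"] = self.errors
        with open(out / "run_metadata.json", "w") as fh:
            json.dump({"metadata": meta, "vaf_curves": curves}, fh, indent=2)


def _condition_seed(config: StudyConfig, cond: ConditionSpec) -> int:
    return config.seed * 128 + cond.grid_index * 2 + LEGS.index(cond.leg)


def _get_activations(
    config: StudyConfig, cond: ConditionSpec, truth: GroundTruth | None
) -> np.ndarray:
    if config.data_source == "synthetic":
        assert truth is not None
        return synthesize_activations(truth, cond)
    base = Path(config.input_dir)  # type: ignore[arg-type]
    for suffix in (".csv", ".sto"):
        path = base / f"{cond.label()}{suffix}"
        if path.exists():
            E, _names = load_activation_file(path)
            return E
    raise FileNotFoundError(
        f"no activation file for condition {cond.label()!r} in {base}"
    )


def run_study(config: StudyConfig) -> SummaryTables:
    """Run the full study analogue and return its summary tables.

    A failure in one condition is recorded in ``errors`` and does not abort
    the rest of the run; the reference condition itself must succeed.
    """
    mset = get_muscle_set(config.muscle_set)
    truth: GroundTruth | None = None
    if config.data_source == "synthetic":
        truth = make_ground_truth(
            mset,
            n_modules=config.n_modules_true,
            noise_sd=config.noise_sd,
            seed=config.seed,
            gains=config.gains,
        )

    module_number_rows: list[dict] = []
    structure_rows: list[dict] = []
    recon_rows: list[dict] = []
    metric_rows: list[dict] = []
    bilateral_rows: list[dict] = []
    curves: dict[str, VafCurve] = {}
    errors: list[dict] = []
    extractions: dict[str, ExtractionResult] = {}

    # Pass 1: reference extraction per leg (must succeed).  The reference
    # patterns used in recruitment comparisons are the NNLS-reconstructed
    # C of the reference condition with its own W, so the reference row's
    # DTW is zero by construction.
    references: dict[str, tuple[ExtractionResult, np.ndarray, np.ndarray]] = {}
    for leg in config.legs:
        ref = reference_condition(leg, config.muscle_set)
        E_ref = _get_activations(config, ref, truth)
        curve = vaf_curve(
            E_ref,
            config.n_max,
            replicates=config.replicates,
            seed=_condition_seed(config, ref),
            max_iter=config.max_iter,
            tol=config.tol,
        )
        n_ref = curve.smallest_n_above(config.primary_threshold) or config.n_max
        res = nmf_decompose(
            E_ref,
            n_ref,
            seed=_condition_seed(config, ref),
            max_iter=config.max_iter,
            tol=config.tol,
            replicates=config.replicates,
        )
        ref_C = reconstruct_with_fixed_modules(res.W, E_ref).C_reconstruct
        references[leg] = (res, E_ref, ref_C)
        curves[ref.label()] = curve

    # Pass 2: every condition.
    for leg in config.legs:
        ref_res, _E_ref, ref_C = references[leg]
        for cond in condition_grid(leg, config.muscle_set):
            try:
                E = _get_activations(config, cond, truth)
                seed_c = _condition_seed(config, cond)
                if cond.label() in curves:
                    curve = curves[cond.label()]
                else:
                    curve = vaf_curve(
                        E,
                        config.n_max,
                        replicates=config.replicates,
                        seed=seed_c,
                        max_iter=config.max_iter,
                        tol=config.tol,
                    )
                    curves[cond.label()] = curve
                base_row = {
                    "speed": cond.speed,
                    "asymmetry": cond.asymmetry,
                    "step_width": cond.step_width,
                    "leg": leg,
                    "is_reference": cond.is_reference,
                }
                for th in sorted(config.vaf_thresholds):
                    n_sel = curve.smallest_n_above(th)
                    module_number_rows.append(
                        {
                            **base_row,
                            "threshold": th,
                            "n_modules": n_sel if n_sel is not None else config.n_max,
                            "threshold_reached": n_sel is not None,
                        }
                    )
                n_primary = (
                    curve.smallest_n_above(config.primary_threshold) or config.n_max
                )
                if cond.is_reference:
                    res = ref_res
                else:
                    res = nmf_decompose(
                        E,
                        n_primary,
                        seed=seed_c,
                        max_iter=config.max_iter,
                        tol=config.tol,
                        replicates=config.replicates,
                    )
                extractions[cond.label()] = res

                pairing = match_modules(ref_res.W, res.W)
                structure_rows.append(
                    {
                        **base_row,
                        "n_modules": res.n_modules,
                        "mean_r": pairing.mean_r,
                        "min_r": float(pairing.r_values.min()),
                        "max_r": float(pairing.r_values.max()),
                        **{
                            f"r_module_{i + 1}": float(r)
                            for (i, _j), r in zip(pairing.pairs, pairing.r_values)
                        },
                    }
                )

                recon = reconstruct_with_fixed_modules(ref_res.W, E)
                recon_rows.append(
                    {**base_row, "reconstruction_vaf": recon.vaf}
                )

                for i in range(ref_res.n_modules):
                    c_rec = recon.C_reconstruct[i]
                    c_ref = ref_C[i]
                    try:
                        coa = center_of_activity(c_rec).fraction
                    except ValueError:
                        coa = float("nan")
                    metric_rows.append(
                        {
                            **base_row,
                            "module": i + 1,
                            "max_activation": peak_activation(c_rec),
                            "coa_fraction": coa,
                            "dtw_to_reference": dtw_distance(c_rec, c_ref),
                        }
                    )
            except Exception as exc:  # single-condition failure: record, continue
                logger.exception("condition %s failed", cond.label())
                errors.append({"condition": cond.label(), "error": str(exc)})

    # Bilateral similarity (needs both legs).
    if set(config.legs) == set(LEGS):
        for cond in condition_grid("left", config.muscle_set):
            left = extractions.get(cond.label())
            right = extractions.get(cond.with_leg("right").label())
            if left is None or right is None:
                continue
            bil = bilateral_similarity(left.W, right.W)
            bilateral_rows.append(
                {
                    "speed": cond.speed,
                    "asymmetry": cond.asymmetry,
                    "step_width": cond.step_width,
                    "mean_r": bil.mean_r,
                    "min_r": bil.min_r,
                    "max_r": bil.max_r,
                }
            )

    tables = SummaryTables(
        module_number=pd.DataFrame(module_number_rows),
        structure_similarity=pd.DataFrame(structure_rows),
        reconstruction_vaf=pd.DataFrame(recon_rows),
        activation_metrics=pd.DataFrame(metric_rows),
        bilateral=pd.DataFrame(bilateral_rows),
        vaf_curves=curves,
        metadata={
            "seed": config.seed,
            "config": config.to_jsonable(),
            "config_hash": config.config_hash(),
            "motormod_version": __version__,
            "numpy_version": np.__version__,
        },
        errors=errors,
        ground_truth=truth,
    )
    if config.output_dir is not None:
        tables.write(config.output_dir)
    return tables


__all__ = ["StudyConfig", "SummaryTables", "run_study"]
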