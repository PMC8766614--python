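"""End-to-end reproduction runs: generation -> analysis -> report.

A pipeline is a named sequence of stages, each a pure function of the
previous stage's files plus a config dict and a seed.  Every stage writes
its artifact together with a provenance JSON (seed, parameters, package
version, input hashes) so stochastic runs can be reproduced byte-for-byte.

Two demo pipelines ship with the package:

* ``masterplot`` — generate a synthetic (kappa, G_eff) master dataset from
  the quadratic rigidity law and fit the scaling (A, kappa_crit, beta);
* ``flicker``    — generate a fluctuating-contour movie at a prescribed
  stiffness, track it, and report Sigma and K_eff.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import __version__

__all__ = ["PipelineError", "RunConfig", "run_pipeline", "DEMO_PIPELINES"]


class PipelineError(RuntimeError):
    """Raised with the failing stage's name and offending field."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    pipeline: str
    out_dir: Path
    seed: int = 0
    params: dict = field(default_factory=dict)
    force: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _provenance(artifact: Path, seed: int, params: dict,
                inputs: list[Path]) -> None:
    artifact.with_suffix(artifact.suffix + ".prov.json").write_text(
        json.dumps(
            dict(
                seed=seed,
                params=params,
                version=__version__,
                inputs={str(p): _sha256(p) for p in inputs},
            ),
            indent=2,
            default=str,
        )
    )


def _stage_master_generate(cfg: RunConfig) -> Path:
    from .synthetic import gen_master_dataset

    out = cfg.out_dir / "master_dataset.csv"
    df = gen_master_dataset(seed=cfg.seed, **cfg.params.get("master", {}))
    df.to_csv(out, index=False)
    _provenance(out, cfg.seed, cfg.params.get("master", {}), [])
    return out


def _stage_master_fit(cfg: RunConfig, inp: Path) -> Path:
    import pandas as pd

    from .fitting import fit_master_scaling

    df = pd.read_csv(inp)
    if "kappa" not in df or "G_eff" not in df:
        raise PipelineError(
            "master_fit", "input is missing column 'kappa' or 'G_eff'"
        )
    res = fit_master_scaling(df, seed=cfg.seed,
                             **cfg.params.get("master_fit", {}))
    out = cfg.out_dir / "master_fit.json"
    out.write_text(
        json.dumps(
            dict(
                A_amp=res.law.A_amp,
                kappa_crit=res.law.kappa_crit,
                beta=res.law.beta,
                beta_conditional=res.beta_conditional,
                stderr=res.stderr,
                warn=res.warn,
            ),
            indent=2,
            default=float,
        )
    )
    _provenance(out, cfg.seed, cfg.params.get("master_fit", {}), [inp])
    return out


def _stage_flicker_generate(cfg: RunConfig) -> Path:
    import tifffile

    from .synthetic import OpticsConfig, gen_contour_series, gen_image_stack

    p = dict(K_eff=200.0, A_mem=float(np.pi * 3.0), n_frames=120,
             radius_um=1.5, n_spatial_modes=8)
    p.update(cfg.params.get("flicker", {}))
    optics = OpticsConfig(n_frames=int(p["n_frames"]))
    series = gen_contour_series(
        p["K_eff"], p["A_mem"], optics=optics, seed=cfg.seed,
        radius_um=p["radius_um"], n_spatial_modes=p["n_spatial_modes"],
    )
    stack = gen_image_stack(series, optics, seed=cfg.seed + 1)
    out = cfg.out_dir / "flicker_stack.tif"
    tifffile.imwrite(out, stack)
    _provenance(out, cfg.seed, p, [])
    return out


def _stage_flicker_analyze(cfg: RunConfig, inp: Path) -> Path:
    import tifffile

    from .flicker import (
        SegmentationConfig,
        effective_stiffness,
        fluctuation_map,
        segment_contours,
    )

    stack = tifffile.imread(inp)
    if stack.ndim != 3:
        raise PipelineError("flicker_analyze", "stack is not 3-D (t, y, x)")
    H, W = stack.shape[1:]
    cfg_seg = SegmentationConfig(**cfg.params.get("segmentation", {}))
    series = segment_contours(
        stack, ((H - 1) / 2.0, (W - 1) / 2.0, min(H, W) / 4.0), cfg_seg
    )
    fmap = fluctuation_map(series)
    A_mem = cfg.params.get("flicker", {}).get("A_mem", float(np.pi * 3.0))
    est = effective_stiffness(fmap, A_mem)
    out = cfg.out_dir / "stiffness_report.json"
    out.write_text(
        json.dumps(
            dict(Sigma_nm=est.Sigma, A_um2=est.A_mem, K_eff=est.K_eff,
                 n_flagged=int(series.flagged_frames.size)),
            indent=2,
        )
    )
    _provenance(out, cfg.seed, cfg.params, [inp])
    return out


DEMO_PIPELINES: dict[str, list[Callable]] = {
    "masterplot": [_stage_master_generate, _stage_master_fit],
    "flicker": [_stage_flicker_generate, _stage_flicker_analyze],
}


def run_pipeline(config: RunConfig) -> list[Path]:
    """Execute the named pipeline's stages in order.

    Returns the list of artifacts written.  The first failing stage aborts
    the run with a :class:`PipelineError` naming it.
    """
    if config.pipeline not in DEMO_PIPELINES:
        raise PipelineError(
            config.pipeline, f"unknown pipeline; have {sorted(DEMO_PIPELINES)}"
        )
    config.out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    prev: Path | None = None
    for stage in DEMO_PIPELINES[config.pipeline]:
        name = stage.__name__
        try:
            prev = stage(config) if prev is None else stage(config, prev)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise PipelineError(name, str(exc)) from exc
        artifacts.append(prev)
    return artifacts
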