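"""Synthetic trial-level lateralization datasets.

Emulates the behavioral study design: 10 listeners, each completing 20
blocks of 55 trials (every combination of 11 ITDs from -375 to +375 us in
75 us steps and 5 sensation levels 5-25 dB SL appears exactly once per
block, in random order).  Responses are the NLME model mean plus additive
Gaussian noise, optionally clipped to the [-1, 1] touchscreen range;
per-listener random effects (midline shift, lateralization amplitude) and
a pure-tone-average (PTA) covariate are drawn once per listener.

Generation is bit-reproducible: all randomness flows from the single
``seed`` through numpy's PCG64 generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .psychometrics import FixedEffects, predict_laterality
from .stimuli import ParameterError

__all__ = ["DesignSpec", "GenerativeTruth", "generate_dataset",
           "generate_model_comparison_dataset"]


@dataclass(frozen=True)
class DesignSpec:
    """The behavioral testing design (defaults reproduce the full study)."""

    n_listeners: int = 10
    itd_grid_us: tuple = tuple(np.arange(-375.0, 376.0, 75.0))
    sl_grid_db: tuple = (5.0, 10.0, 15.0, 20.0, 25.0)
    n_blocks: int = 20
    pta_range_db: tuple[float, float] = (0.0, 25.0)  # normal-hearing cut-off
    experiment: str = "flat"

    @property
    def trials_per_block(self) -> int:
        return len(self.itd_grid_us) * len(self.sl_grid_db)

    @property
    def trials_per_listener(self) -> int:
        return self.n_blocks * self.trials_per_block

    def __post_init__(self) -> None:
        if self.n_listeners < 1 or self.n_blocks < 1:
            raise ParameterError("need at least one listener and block")
        if len(set(self.itd_grid_us)) < 2 or len(set(self.sl_grid_db)) < 2:
            raise ParameterError("ITD and SL grids need at least two values")


@dataclass(frozen=True)
class GenerativeTruth:
    """Generating parameters: the generative counterpart of the NLME model.

    ``amplitude_mean`` is the population mean of the by0 amplitude term
    (the model equation carries no separate fixed amplitude).  Clipping is
    off by default because the hard [-1, 1] bound biases parameter
    recovery; switch it on for realism demonstrations.
    """

    fixed: FixedEffects = field(default_factory=lambda: FixedEffects(
        ax0=0.06, ax1=2.45, ax2=0.02, ay1=0.05, ay2=0.01))
    amplitude_mean: float = 1.0
    sigma_x0: float = 0.10
    sigma_y0: float = 0.15
    sigma_resid: float = 0.10
    clip_responses: bool = False
    form: str = "ratio"
    seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["fixed"] = asdict(self.fixed)
        return d


def _block_orders(rng: np.random.Generator, design: DesignSpec) -> np.ndarray:
    """(n_blocks, trials_per_block) permutations of the ITD x SL grid."""
    cells = design.trials_per_block
    return np.stack([rng.permutation(cells) for _ in range(design.n_blocks)])


def generate_dataset(design: DesignSpec | None = None,
                     truth: GenerativeTruth | None = None
                     ) -> tuple[pd.DataFrame, dict]:
    """Generate one complete synthetic study.

    Returns the tidy trial table (``listener_id, experiment, block,
    itd_us, sl_db, pta_db, response``) and a truth sidecar dict holding
    the generating parameters and per-listener random effects, for
    recovery scoring.
    """
    design = design or DesignSpec()
    truth = truth or GenerativeTruth()
    rng = np.random.default_rng(truth.seed)

    itds = np.asarray(design.itd_grid_us, float)
    sls = np.asarray(design.sl_grid_db, float)
    grid = np.array([(i, s) for i in itds for s in sls])
    # z-score predictors against the (balanced) design, as fitting will
    itd_z = (grid[:, 0] - itds.mean()) / itds.std()
    sl_z = (grid[:, 1] - sls.mean()) / sls.std()

    pta = rng.uniform(*design.pta_range_db, design.n_listeners)
    bx0 = rng.normal(0.0, truth.sigma_x0, design.n_listeners)
    by0 = truth.amplitude_mean + rng.normal(0.0, truth.sigma_y0,
                                            design.n_listeners)

    frames = []
    for l in range(design.n_listeners):
        order = _block_orders(rng, design)          # (blocks, cells)
        idx = order.ravel()
        mean = predict_laterality(truth.fixed, bx0[l], by0[l], pta[l],
                                  itd_z[idx], sl_z[idx], truth.form)
        resp = mean + rng.normal(0.0, truth.sigma_resid, mean.size)
        if truth.clip_responses:
            resp = np.clip(resp, -1.0, 1.0)
        frames.append(pd.DataFrame({
            "listener_id": f"L{l:02d}",
            "experiment": design.experiment,
            "block": np.repeat(np.arange(design.n_blocks), order.shape[1]),
            "itd_us": grid[idx, 0],
            "sl_db": grid[idx, 1],
            "pta_db": pta[l],
            "response": resp,
        }))
    trials = pd.concat(frames, ignore_index=True)
    sidecar = {
        "truth": truth.as_dict(),
        "design": {"n_listeners": design.n_listeners,
                   "n_blocks": design.n_blocks,
                   "trials_per_block": design.trials_per_block,
                   "experiment": design.experiment},
        "listeners": {f"L{l:02d}": {"pta_db": float(pta[l]),
                                    "bx0": float(bx0[l]),
                                    "by0": float(by0[l])}
                      for l in range(design.n_listeners)},
    }
    return trials, sidecar


def generate_model_comparison_dataset(
        truth_ll: GenerativeTruth | None = None,
        truth_hemi: GenerativeTruth | None = None,
        design: DesignSpec | None = None,
        ll_noise_gain: float = 1.5,
) -> dict[str, tuple[pd.DataFrame, dict]]:
    """Paired datasets realizing the two codes' behavioral signatures.

    The rate-code ("hemifield") dataset has lateralization amplitude
    growing with sensation level (positive intensity-on-amplitude effect);
    the place-code ("labelled_line") dataset has level-*independent* mean
    laterality but response noise that grows toward low level (scaled up
    by ``1 + ll_noise_gain`` at the softest level), the two models'
    respective predictions.  Both share the design; identical seeds and
    truths give identical datasets.
    """
    design = design or DesignSpec()
    truth_hemi = truth_hemi or GenerativeTruth()   # ay1 > 0 by default
    if truth_ll is None:
        base = GenerativeTruth()
        truth_ll = GenerativeTruth(
            fixed=FixedEffects(ax0=base.fixed.ax0, ax1=base.fixed.ax1,
                               ax2=0.0, ay1=0.0, ay2=base.fixed.ay2),
            amplitude_mean=base.amplitude_mean, sigma_x0=base.sigma_x0,
            sigma_y0=base.sigma_y0, sigma_resid=base.sigma_resid,
            clip_responses=base.clip_responses, seed=base.seed)

    hemi = generate_dataset(design, truth_hemi)

    # labelled line: same pipeline, then re-noise with level-dependent sd
    trials, sidecar = generate_dataset(design, truth_ll)
    rng = np.random.default_rng(np.random.SeedSequence([truth_ll.seed, 1]))
    sls = np.asarray(design.sl_grid_db, float)
    span = sls.max() - sls.min()
    rel = (sls.max() - trials["sl_db"].to_numpy(float)) / span
    sd = truth_ll.sigma_resid * (1.0 + ll_noise_gain * rel)
    # strip the original homoscedastic noise by regenerating from the mean
    trials2, _ = generate_dataset(design, GenerativeTruth(
        **{**truth_ll.as_dict(), "fixed": truth_ll.fixed,
           "sigma_resid": 0.0}))
    mean = trials2["response"].to_numpy(float)
    resp = mean + rng.normal(0.0, 1.0, mean.size) * sd
    if truth_ll.clip_responses:
        resp = np.clip(resp, -1.0, 1.0)
    trials2["response"] = resp
    sidecar["noise_profile"] = {float(s): float(truth_ll.sigma_resid
                                                * (1 + ll_noise_gain
                                                   * (sls.max() - s) / span))
                                for s in sls}
    return {"hemifield": hemi, "labelled_line": (trials2, sidecar)}
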