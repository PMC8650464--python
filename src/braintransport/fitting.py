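"""Grid-search estimation of subdomain effective diffusivities.

The objective is the root-mean-square mismatch between simulated and
measured nodal concentration,

    rms = sqrt( sum (c_data - c_sim)^2 / T )

over all included node-frame residuals, where nodes touching excluded
subdomains (artery, ventricle), nodes within a ball around the injection
site, and frames beyond the fit horizon are dropped.  The search is
exhaustive over a (typically log-spaced) Deff grid, one forward solve
per triplet, with the full error surface retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretization import Mesh, NodalField
from .solver import FunctionSpace, SolverConfig, SourceSpec, TransportParams, solve_transport
from .subdomains import Subdomain

__all__ = ["ErrorMaskSpec", "FitResult", "rms_error", "grid_search"]


@dataclass
class ErrorMaskSpec:
    exclude_tags: tuple[int, ...] = (int(Subdomain.ARTERY), int(Subdomain.VENTRICLE))
    injection_radius: float = 0.5  # mm
    injection_site: tuple[float, float, float] | None = None  # mm
    max_fit_time: float = 52.0  # min

    def __post_init__(self) -> None:
        if self.injection_radius < 0:
            raise ValueError("injection exclusion radius must be >= 0")

    def node_mask(self, coords: np.ndarray, tagbits: np.ndarray | None) -> np.ndarray:
        """Boolean include-mask over nodes."""
        keep = np.ones(coords.shape[0], dtype=bool)
        if tagbits is not None and self.exclude_tags:
            bits = np.uint16(0)
            for t in self.exclude_tags:
                bits |= np.uint16(1) << np.uint16(t)
            keep &= (tagbits & bits) == 0
        if self.injection_site is not None and self.injection_radius > 0:
            d = np.linalg.norm(coords - np.asarray(self.injection_site), axis=1)
            keep &= d > self.injection_radius
        return keep

    def frame_mask(self, times: np.ndarray) -> np.ndarray:
        return np.asarray(times) <= self.max_fit_time + 1e-9


@dataclass
class FitResult:
    grid: list[tuple[float, float, float]]  # (BT, PAS_Surf, PAS_Branch)
    rms: list[float]
    optimum: tuple[float, float, float]
    optimum_rms: float
    per_frame_rms: dict[float, float] = field(default_factory=dict)
    failed: list[tuple[float, float, float]] = field(default_factory=list)
    n_residuals: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.grid, columns=["deff_bt", "deff_surf", "deff_branch"])
        df["rms"] = self.rms
        df["n_points"] = self.n_residuals
        return df

    def to_dict(self) -> dict:
        return {
            "optimum": list(self.optimum),
            "optimum_rms": self.optimum_rms,
            "n_residuals": self.n_residuals,
            "per_frame_rms": {str(k): v for k, v in self.per_frame_rms.items()},
            "surface": [
                {"deff": list(g), "rms": r} for g, r in zip(self.grid, self.rms)
            ],
            "failed": [list(g) for g in self.failed],
        }


def _residuals(sim: NodalField, data: NodalField, mask: ErrorMaskSpec):
    if sim.values.shape != data.values.shape:
        raise ValueError("sim/data shape mismatch")
    if sim.times is None or data.times is None:
        raise ValueError("both stacks need frame times")
    if not np.allclose(sim.times, data.times):
        raise ValueError("sim/data frame times differ")
    tagbits = sim.tagbits if sim.tagbits is not None else data.tagbits
    keep_n = mask.node_mask(sim.coords, tagbits)
    keep_t = mask.frame_mask(sim.times)
    if not keep_n.any() or not keep_t.any():
        raise ValueError("error mask excludes every node-frame pair")
    res = (data.values - sim.values)[np.ix_(keep_n, keep_t)]
    return res, keep_t


def rms_error(sim: NodalField, data: NodalField, mask: ErrorMaskSpec) -> float:
    """Eq.-style rms over all included node-frame residuals (mM)."""
    res, _ = _residuals(sim, data, mask)
    return float(np.sqrt(np.mean(res ** 2)))


def grid_search(
    data: NodalField,
    mesh: Mesh,
    grid_bt,
    grid_surf,
    grid_branch,
    source: SourceSpec,
    cfg: SolverConfig | None = None,
    mask: ErrorMaskSpec | None = None,
    blocked_fraction: float = 1e-8,
    sim_cache: dict | None = None,
    partial: dict | None = None,
) -> FitResult:
    """Exhaustive search over Deff triplets (BT, PAS_Surf, PAS_Branch).

    One forward solve per triplet (reused from ``sim_cache`` when
    provided, enabling cheap refits against new data); ``partial`` maps
    already-evaluated triplets to rms for resuming.  The optimum is the
    minimal rms with lexicographically-smallest-triplet tie-break.
    Failed solves are recorded and excluded.
    """
    cfg = cfg or SolverConfig()
    mask = mask or ErrorMaskSpec()
    grid = [
        (float(b), float(s), float(br))
        for b, s, br in itertools.product(grid_bt, grid_surf, grid_branch)
    ]
    if not grid:
        raise ValueError("empty search grid")

    # only frames inside the fit horizon need forward solves
    keep_t = mask.frame_mask(data.times)
    if not keep_t.any():
        raise ValueError("fit horizon excludes every frame")
    fit_times = np.asarray(data.times)[keep_t]
    data_fit = NodalField(
        values=data.values[:, keep_t], coords=data.coords, times=fit_times,
        tagbits=data.tagbits,
    )

    space = FunctionSpace(mesh, cfg.element_order)
    rms_list: list[float] = []
    failed: list[tuple[float, float, float]] = []
    n_res = 0
    best: tuple[float, tuple[float, float, float]] | None = None
    best_sim: NodalField | None = None

    for trip in grid:
        if partial is not None and trip in partial:
            r = float(partial[trip])
            rms_list.append(r)
            if best is None or (r, trip) < best:
                best, best_sim = (r, trip), None
            continue
        try:
            if sim_cache is not None and trip in sim_cache:
                sim = sim_cache[trip]
            else:
                params = TransportParams(
                    deff={
                        int(Subdomain.BT): trip[0],
                        int(Subdomain.PAS_SURF): trip[1],
                        int(Subdomain.PAS_BRANCH): trip[2],
                    },
                    blocked_fraction=blocked_fraction,
                )
                sim = solve_transport(mesh, params, source, fit_times, cfg, space=space)
                if sim_cache is not None:
                    sim_cache[trip] = sim
            res, _ = _residuals(sim, data_fit, mask)
            r = float(np.sqrt(np.mean(res ** 2)))
            n_res = res.size
        except np.linalg.LinAlgError as exc:  # solver failure: skip triplet
            failed.append(trip)
            rms_list.append(np.nan)
            continue
        rms_list.append(r)
        if best is None or (r, trip) < best:
            best, best_sim = (r, trip), sim

    if best is None:
        raise RuntimeError("every triplet in the grid failed")

    per_frame: dict[float, float] = {}
    if best_sim is not None:
        keep_n = mask.node_mask(best_sim.coords, best_sim.tagbits)
        diff = (data_fit.values - best_sim.values)[keep_n]
        for j, t in enumerate(fit_times):
            per_frame[float(t)] = float(np.sqrt(np.mean(diff[:, j] ** 2)))

    return FitResult(
        grid=grid,
        rms=rms_list,
        optimum=best[1],
        optimum_rms=best[0],
        per_frame_rms=per_frame,
        failed=failed,
        n_residuals=n_res,
    )
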