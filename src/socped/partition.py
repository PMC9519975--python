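"""Variance partitioning: repeatability, heritability, maternal effects.

Every statistic is computed draw-wise on the posterior chain and only then
summarized (posterior mode of the ratio draws, never the ratio of modes).
Total phenotypic variance V_P is the sum of the ten variance components
(nine grouping terms plus the residual); optionally the variance explained
by the fixed effects (V_FE, itself a per-draw quantity Var_records(X beta))
is added to the denominator.

Reported quantities: the per-component variance proportions, narrow-sense
heritability h2 = V_A / V_P, maternal effect m2 = V_M / V_P, permanent
environment effect pe2 = V_ID / V_P, long-term repeatability
R_long = (V_ID + V_M + V_A) / V_P, and short-term repeatability
R_short = (V_ID + V_ID:Year + V_M + V_M:GroupAlpha:Year + V_A) / V_P.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .animal_model import PosteriorChain, hpd_interval, posterior_mode

__all__ = [
    "PartitionSummary",
    "fixed_effect_variance",
    "full_report",
    "partition_draws",
    "report",
    "render_report",
    "parse_report",
]

LONG_TERM = ("V_ID", "V_M", "V_A")
SHORT_TERM = ("V_ID", "V_ID:Year", "V_M", "V_M:GroupAlpha:Year", "V_A")


@dataclass
class PartitionSummary:
    """Posterior mode + 95% HPD per quantity, plus the per-draw table.

    ``proportions`` maps each variance component to (mode, lo, hi);
    ``quantities`` holds h2, m2, pe2, R_long, R_short the same way.
    ``draws`` retains the per-draw values for identity checks and plotting.
    """

    proportions: dict
    quantities: dict
    v_fe_in_denominator: bool
    scale: str  # "latent" | "data"
    draws: pd.DataFrame = field(repr=False)

    def mode(self, name: str) -> float:
        src = self.quantities if name in self.quantities else self.proportions
        return src[name][0]

    def hpd(self, name: str) -> tuple[float, float]:
        src = self.quantities if name in self.quantities else self.proportions
        return src[name][1], src[name][2]


def fixed_effect_variance(X: np.ndarray, beta_draws: np.ndarray) -> np.ndarray:
    """Per-draw variance across records of the linear predictor X beta.

    ``beta_draws`` has one row per draw.  The design matrix must exclude any
    offset column (sampling-effort offsets are not part of V_FE).  The
    population variance (ddof 0) matches the z-scoring convention of the
    design builder, so a single z-scored covariate with slope b gives b^2.
    """
    X = np.asarray(X, float)
    beta_draws = np.atleast_2d(np.asarray(beta_draws, float))
    if X.shape[1] != beta_draws.shape[1]:
        raise ValueError(
            f"design has {X.shape[1]} columns but draws have {beta_draws.shape[1]}"
        )
    pred = beta_draws @ X.T  # (draws, records)
    return pred.var(axis=1, ddof=0)


def _summary(x: np.ndarray, prob: float = 0.95) -> tuple[float, float, float]:
    lo, hi = hpd_interval(x, prob)
    return posterior_mode(x), lo, hi


def partition_draws(
    chain: PosteriorChain,
    v_fe: np.ndarray | None = None,
    scale: str = "latent",
) -> PartitionSummary:
    """Partition the posterior into per-component proportions and ratios.

    ``v_fe`` is an optional per-draw fixed-effect variance (same length as
    the chain); when supplied it enters the denominator draw-wise.
    """
    comps = chain.variance_components
    for needed in set(LONG_TERM) | set(SHORT_TERM) | {"V_residual"}:
        if needed not in comps:
            raise ValueError(f"missing component {needed!r} in chain")
    V = chain.draws[comps].to_numpy(float)
    vp = V.sum(axis=1)
    if v_fe is not None:
        v_fe = np.asarray(v_fe, float)
        if len(v_fe) != len(vp):
            raise ValueError("v_fe length must match the number of draws")
        vp = vp + v_fe

    draws = pd.DataFrame(
        {f"p:{c}": chain.draws[c].to_numpy(float) / vp for c in comps}
    )
    by = {c: chain.draws[c].to_numpy(float) for c in comps}
    draws["h2"] = by["V_A"] / vp
    draws["m2"] = by["V_M"] / vp
    draws["pe2"] = by["V_ID"] / vp
    draws["R_long"] = sum(by[c] for c in LONG_TERM) / vp
    draws["R_short"] = sum(by[c] for c in SHORT_TERM) / vp
    if v_fe is not None:
        draws["v_fe"] = v_fe

    proportions = {c: _summary(draws[f"p:{c}"].to_numpy()) for c in comps}
    quantities = {
        q: _summary(draws[q].to_numpy())
        for q in ("h2", "m2", "pe2", "R_long", "R_short")
    }
    return PartitionSummary(
        proportions=proportions,
        quantities=quantities,
        v_fe_in_denominator=v_fe is not None,
        scale=scale,
        draws=draws,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(
    summary: PartitionSummary,
    transformed: pd.DataFrame | None = None,
) -> dict:
    """Machine-readable report: mode + 95% HPD per quantity per scale.

    ``transformed`` optionally supplies a data-scale posterior (per-draw
    ``ratio_obs`` from :func:`socped.scale_transform.transform_posterior`),
    reported as ``h2_data``.
    """
    out = {
        "scale": summary.scale,
        "v_fe_in_denominator": summary.v_fe_in_denominator,
        "proportions": {
            k: {"mode": v[0], "hpd_lo": v[1], "hpd_hi": v[2]}
            for k, v in summary.proportions.items()
        },
        "quantities": {
            k: {"mode": v[0], "hpd_lo": v[1], "hpd_hi": v[2]}
            for k, v in summary.quantities.items()
        },
    }
    if transformed is not None:
        x = transformed["ratio_obs"].to_numpy(float)
        mode, lo, hi = _summary(x)
        out["data_scale"] = {"h2": {"mode": mode, "hpd_lo": lo, "hpd_hi": hi}}
    return out


def full_report(
    chain: PosteriorChain,
    X: np.ndarray,
    link: str,
    n_obs: int = 1,
    subsample: int | None = None,
    seed: int = 0,
) -> dict:
    """Four-cell heritability grid: latent/data scale x V_FE out/in.

    ``X`` is the fixed-effects design aligned with the chain's beta columns
    (offset excluded).  Returns ``{"latent": {...}, "data": {...}}`` with
    ``vfe_excluded``/``vfe_included`` sub-reports in each.
    """
    from .scale_transform import transform_posterior

    beta_cols = [c for c in chain.draws.columns if c.startswith("beta:")]
    v_fe = fixed_effect_variance(X, chain.draws[beta_cols].to_numpy(float))

    grid: dict = {"latent": {}, "data": {}}
    for flag, fe in (("vfe_excluded", None), ("vfe_included", v_fe)):
        grid["latent"][flag] = report(partition_draws(chain, v_fe=fe))

    tr = transform_posterior(chain, "animal", link, n_obs=n_obs,
                             subsample=subsample, seed=seed)
    comps = chain.variance_components
    for flag, fe in (("vfe_excluded", None), ("vfe_included", v_fe)):
        # data-scale h2: per-draw v_focal_obs over var_obs (+ V_FE on the
        # data scale approximated by the latent V_FE mapped through the
        # same per-draw variance ratio)
        idx = tr.index
        vp_latent = chain.draws.loc[idx, comps].sum(axis=1).to_numpy(float)
        ratio = tr["var_obs"].to_numpy(float) / vp_latent
        denom = tr["var_obs"].to_numpy(float)
        if fe is not None:
            denom = denom + fe[idx] * ratio
        h2_data = tr["v_focal_obs"].to_numpy(float) / denom
        mode, lo, hi = _summary(h2_data)
        grid["data"][flag] = {"h2": {"mode": mode, "hpd_lo": lo, "hpd_hi": hi}}
    return grid


def render_report(rep: dict) -> str:
    """Serialize a report (JSON); inverse of :func:`parse_report`."""
    return json.dumps(rep, indent=2, sort_keys=True)


def parse_report(text: str) -> dict:
    return json.loads(text)


def format_table(rep: dict) -> str:
    """Human-readable aligned table of modes and 95% HPD intervals."""
    lines = [
        f"scale: {rep['scale']}   V_FE in denominator: {rep['v_fe_in_denominator']}",
        f"{'quantity':<24}{'mode':>10}{'hpd_lo':>10}{'hpd_hi':>10}",
    ]
    for section in ("quantities", "proportions"):
        for k, v in rep[section].items():
            lines.append(
                f"{k:<24}{v['mode']:>10.4f}{v['hpd_lo']:>10.4f}{v['hpd_hi']:>10.4f}"
            )
    if "data_scale" in rep:
        v = rep["data_scale"]["h2"]
        lines.append(
            f"{'h2 (data scale)':<24}{v['mode']:>10.4f}{v['hpd_lo']:>10.4f}{v['hpd_hi']:>10.4f}"
        )
    return "\n".join(lines)
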