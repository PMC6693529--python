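"""Study power and required sample size from metric variability.

For two normal populations with means differing by mu and common standard
deviation sigma, measured on N participants per group, the quantity

    Q = sqrt(N) * mu / sigma

determines the power of the study to detect the difference at a chosen
significance level: larger Q, higher power. Keeping Q constant when the
measurement SD changes from sigma_ref to sigma therefore requires the
number of participants to scale by (sigma / sigma_ref)^2. These two pieces
of arithmetic convert the per-scheme SDs of any metric's distribution into
a relative sample-size cost of choosing one graph-construction scheme over
another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["PowerInputs", "power_statistic", "required_n_multiplier", "summarize_power"]


@dataclass(frozen=True)
class PowerInputs:
    """Inputs of the power statistic: group size N, mean difference, common SD."""

    N: int
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def power_statistic(inputs: PowerInputs) -> float:
    """Q = sqrt(N) * mu / sigma."""
    return float(np.sqrt(inputs.N) * inputs.mu / inputs.sigma)


def required_n_multiplier(sigma_scheme: float, sigma_reference: float) -> float:
    """Factor by which N must grow to keep Q constant under an SD change.

    Equals (sigma_scheme / sigma_reference)^2.
    """
    if sigma_scheme <= 0 or sigma_reference <= 0:
        raise ValueError("standard deviations must be positive")
    return float((sigma_scheme / sigma_reference) ** 2)


def summarize_power(
    metric_distributions: Mapping[str, Sequence[float]],
    reference_scheme: Optional[str] = None,
    N: Optional[int] = None,
    mu: Optional[float] = None,
) -> pd.DataFrame:
    """Per-scheme SD, SD ratio and required-N multiplier for one metric.

    Parameters
    ----------
    metric_distributions:
        scheme -> sample of the metric (e.g. per-participant graph
        similarities). Each sample needs at least two values; SDs use the
        n-1 denominator.
    reference_scheme:
        Scheme whose SD anchors the ratios; defaults to the scheme with the
        smallest SD.
    N, mu:
        Optional group size and mean difference; when both are given a Q
        column is added.

    Raises
    ------
    ValueError
        If fewer than two schemes are supplied, a distribution has fewer
        than two values, or the reference scheme's SD is zero (degenerate:
        no variability to compare against), naming the offending scheme.
    """
    if len(metric_distributions) < 2:
        raise ValueError("need at least two schemes to compare")
    sds = {}
    for scheme, values in metric_distributions.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError(f"scheme {scheme!r}: need >= 2 values, got {arr.size}")
        sds[scheme] = float(arr.std(ddof=1))
    if reference_scheme is None:
        reference_scheme = min(sds, key=lambda s: sds[s])
    if reference_scheme not in sds:
        raise ValueError(f"reference scheme {reference_scheme!r} not among distributions")
    ref_sd = sds[reference_scheme]
    if ref_sd == 0:
        raise ValueError(
            f"reference scheme {reference_scheme!r} has zero SD: "
            "power comparison is degenerate"
        )
    rows = []
    for scheme, sd in sds.items():
        ratio = sd / ref_sd
        rows.append(
            {
                "scheme": scheme,
                "sd": sd,
                "sd_ratio": ratio,
                "required_n_multiplier": ratio ** 2,
            }
        )
    df = pd.DataFrame(rows).set_index("scheme")
    df.attrs["reference_scheme"] = reference_scheme
    if N is not None and mu is not None:
        df["Q"] = [
            power_statistic(PowerInputs(N=N, mu=mu, sigma=sd)) if sd > 0 else float("inf")
            for sd in df["sd"]
        ]
    return df
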