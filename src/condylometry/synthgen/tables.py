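"""Simulation of per-subject measurement tables.

Each grouping scheme (symmetry / sagittal / vertical) has fixed group
sizes and per-group normal distributions for the six condylar measurands
(or their side differences). Variables are drawn independently per
variable; an optional per-group covariance matrix turns the draw into a
multivariate normal for sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import SpecValidationError
from . import params as P


@dataclass(frozen=True)
class GroupSimSpec:
    """Specification of a group-structured measurement-table simulation.

    Parameters default to the published group sizes, means and SDs of the
    chosen scheme. ``covariances`` (group -> p×p matrix) optionally adds
    cross-variable covariance; when given, the diagonal overrides ``sds``.
    """

    scheme: str = "symmetry"
    group_sizes: Optional[Mapping[str, int]] = None
    means: Optional[Mapping[str, Sequence[float]]] = None
    sds: Optional[Mapping[str, Sequence[float]]] = None
    covariances: Optional[Mapping[str, np.ndarray]] = None
    seed: int = 0

    def resolved(self) -> dict:
        """Validate and fill defaults; returns a plain dict of parameters."""
        if self.scheme not in P.SCHEMES:
            raise SpecValidationError(
                f"unknown scheme {self.scheme!r}; expected one of {P.SCHEMES}")
        variables = P.scheme_variables(self.scheme)
        defaults = P.GROUP_PARAMETERS[self.scheme]
        groups = list(defaults)
        sizes = dict(self.group_sizes) if self.group_sizes is not None else {
            g: defaults[g]["n"] for g in groups}
        means = {g: np.asarray(
            (self.means or {}).get(g, defaults[g]["means"]), dtype=float)
            for g in groups}
        sds = {g: np.asarray(
            (self.sds or {}).get(g, defaults[g]["sds"]), dtype=float)
            for g in groups}
        for g in groups:
            if g not in sizes or int(sizes[g]) <= 0:
                raise SpecValidationError(f"group size for {g!r} must be positive")
            if means[g].shape != (len(variables),):
                raise SpecValidationError(
                    f"means for group {g!r} must have {len(variables)} entries "
                    f"(variables {variables}), got shape {means[g].shape}")
            if sds[g].shape != (len(variables),):
                raise SpecValidationError(
                    f"sds for group {g!r} must have {len(variables)} entries, "
                    f"got shape {sds[g].shape}")
            if np.any(sds[g] <= 0):
                raise SpecValidationError(f"sds for group {g!r} must be strictly positive")
        covs = None
        if self.covariances is not None:
            covs = {}
            for g in groups:
                C = np.asarray(self.covariances[g], dtype=float)
                if C.shape != (len(variables), len(variables)):
                    raise SpecValidationError(
                        f"covariance for group {g!r} must be "
                        f"{len(variables)}×{len(variables)}")
                covs[g] = C
        return {"variables": variables, "groups": groups, "sizes": sizes,
                "means": means, "sds": sds, "covariances": covs}


def _truncated_group_value(rng, scheme: str, group: str, n: int) -> np.ndarray:
    """Draw the grouping variable consistently with the group's interval."""
    g = P.GROUP_PARAMETERS[scheme][group]
    lo, hi = P.GROUP_INTERVALS[scheme][group]
    mu, sd = g["group_mean"], g["group_sd"]
    a = -np.inf if lo is None else (lo - mu) / sd
    b = np.inf if hi is None else (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def simulate_measurement_table(spec: GroupSimSpec) -> pd.DataFrame:
    """Draw one row per subject from the group-specific distributions.

    Returns a data frame with columns ``subject_id, side, group_scheme,
    group, <grouping variable>, <measurand columns>``. The ``side`` column
    is ``"both"`` — these are per-subject aggregates / side differences.
    Reproducible for a fixed ``spec.seed``.
    """
    r = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    grouping_var = P.GROUPING_VARIABLE[spec.scheme]
    frames = []
    offset = 0
    for g in r["groups"]:
        n = int(r["sizes"][g])
        if r["covariances"] is not None:
            draws = rng.multivariate_normal(
                r["means"][g], r["covariances"][g], size=n)
        else:
            draws = rng.normal(r["means"][g], r["sds"][g],
                               size=(n, len(r["variables"])))
        df = pd.DataFrame(draws, columns=list(r["variables"]))
        df.insert(0, "subject_id", [f"S{offset + i + 1:04d}" for i in range(n)])
        df.insert(1, "side", "both")
        df.insert(2, "group_scheme", spec.scheme)
        df.insert(3, "group", g)
        df.insert(4, grouping_var,
                  _truncated_group_value(rng, spec.scheme, g, n))
        frames.append(df)
        offset += n
    return pd.concat(frames, ignore_index=True)
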