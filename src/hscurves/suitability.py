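"""Habitat availability, utilization and preference curves, SI normalization,
and combination of campaigns into final habitat suitability curves.

The machinery follows the classic use/availability construction:

* HAC (availability), P[E](i) = a_i / sum(a_i), where a_i is the sampled
  habitat area falling in parameter bin i;
* HUC (utilization), P[E/F](i) = u_i / sum(u_i), where u_i is the (campaign-
  standardized) organism abundance recorded in bin i;
* HPC (preference), P_r(i) = P[E/F](i) / P[E](i), defined only where habitat
  was actually available (P[E] > 0) — unavailable bins are masked, never
  imputed as zero suitability;
* SI, each curve divided by its maximum so the best bin scores 1.

Continuous parameters are binned half-open [lo, hi) with the last bin closed,
0.05-unit wide by default for both velocity (m/s) and depth (m).  Because the
same conditions are not on offer at different discharges, curves are built
per campaign first and only then merged: the final suitability at a bin is
driven by the best evidence any campaign provides there, optionally widened
into a contiguous SI = 1 plateau between high-suitability bins
(``envelope_fill``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import SUBSTRATE_CODES, SampleRecord
from .ffg import FFGMembership, project_counts

__all__ = [
    "BinScheme",
    "CurveSet",
    "FinalCurve",
    "ExcessReport",
    "default_bins",
    "sample_value",
    "standardize_by_campaign",
    "availability_curve",
    "utilization_curve",
    "preference_curve",
    "to_si",
    "huc_hac_excess",
    "build_curve_set",
    "combine_campaigns",
]

PARAMETERS: tuple[str, ...] = ("velocity", "depth", "substrate")


@dataclass(frozen=True)
class BinScheme:
    """Binning of one habitat parameter.

    Continuous schemes carry strictly increasing ``edges``; bin i covers
    [edges[i], edges[i+1]) except the last bin, which also includes its upper
    edge.  Categorical schemes carry an ordered tuple of category codes.
    """

    parameter: str
    kind: str  # "continuous" | "categorical"
    edges: tuple[float, ...] = ()
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if len(self.edges) < 2:
                raise ValueError("continuous scheme needs at least 2 edges")
            if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
                raise ValueError("edges must be strictly increasing")
        elif self.kind == "categorical":
            if not self.categories:
                raise ValueError("categorical scheme needs at least one category")
            if len(set(self.categories)) != len(self.categories):
                raise ValueError("categories must be unique")
        else:
            raise ValueError(f"unknown bin kind {self.kind!r}")

    @property
    def n_bins(self) -> int:
        if self.kind == "continuous":
            return len(self.edges) - 1
        return len(self.categories)

    def index(self, value: float | str) -> int:
        """Bin index of a parameter value; raises if out of range."""
        if self.kind == "categorical":
            try:
                return self.categories.index(value)  # type: ignore[arg-type]
            except ValueError:
                raise ValueError(
                    f"{self.parameter}: unknown category {value!r}"
                ) from None
        v = float(value)  # type: ignore[arg-type]
        if v == self.edges[-1]:
            return self.n_bins - 1
        i = int(np.searchsorted(self.edges, v, side="right")) - 1
        if i < 0 or i >= self.n_bins:
            raise ValueError(
                f"{self.parameter}: value {v} outside bin range "
                f"[{self.edges[0]}, {self.edges[-1]}]"
            )
        return i

    def labels(self) -> tuple[str, ...]:
        if self.kind == "categorical":
            return self.categories
        return tuple(
            f"{lo:g}-{hi:g}" for lo, hi in zip(self.edges, self.edges[1:])
        )

    def bounds(self) -> tuple[tuple[float, float], ...]:
        if self.kind != "continuous":
            raise ValueError("bounds() only defined for continuous schemes")
        return tuple(zip(self.edges, self.edges[1:]))


def default_bins(
    parameter: str,
    data_max: float | None = None,
    width: float = 0.05,
    substrate_codes: Sequence[str] = SUBSTRATE_CODES,
) -> BinScheme:
    """Default bin scheme: 0.05-unit bins from 0 for velocity/depth, the six
    substrate categories for substrate."""
    if parameter == "substrate":
        return BinScheme(
            parameter="substrate", kind="categorical",
            categories=tuple(substrate_codes),
        )
    if parameter not in ("velocity", "depth"):
        raise ValueError(f"unknown parameter {parameter!r}")
    if data_max is None:
        raise ValueError(f"{parameter}: data_max required for continuous bins")
    if width <= 0:
        raise ValueError("bin width must be positive")
    n = max(1, math.ceil(data_max / width - 1e-9))
    edges = tuple(round(i * width, 10) for i in range(n + 1))
    return BinScheme(parameter=parameter, kind="continuous", edges=edges)


def sample_value(sample: SampleRecord, parameter: str) -> float | str:
    """The habitat parameter value of one sample."""
    if parameter == "velocity":
        return sample.velocity
    if parameter == "depth":
        return sample.depth
    if parameter == "substrate":
        return sample.substrate
    raise ValueError(f"unknown parameter {parameter!r}")


def standardize_by_campaign(
    samples: Iterable[SampleRecord],
    membership: FFGMembership,
    group: str,
) -> dict[str, float]:
    """Per-sample group abundance divided by its campaign's maximum.

    Puts campaigns sampled at different discharges (hence different overall
    abundance levels) on a common [0, 1] scale before they are pooled.  A
    campaign where the group is entirely absent contributes zeros (with a
    warning) rather than failing.
    """
    samples = list(samples)
    by_campaign: dict[str, list[SampleRecord]] = {}
    for s in samples:
        by_campaign.setdefault(s.campaign_id, []).append(s)
    out: dict[str, float] = {}
    for campaign, members in by_campaign.items():
        abundances = {s.sample_id: project_counts(s, membership, group)
                      for s in members}
        peak = max(abundances.values(), default=0)
        if peak == 0:
            warnings.warn(
                f"group {group}: no individuals in campaign {campaign!r}; "
                "its standardized abundances are all zero",
                stacklevel=2,
            )
            out.update({sid: 0.0 for sid in abundances})
        else:
            out.update({sid: a / peak for sid, a in abundances.items()})
    return out


def availability_curve(
    samples: Sequence[SampleRecord], bins: BinScheme
) -> np.ndarray:
    """P[E]: share of sampled habitat area per bin (sums to 1)."""
    if not samples:
        raise ValueError("availability curve needs at least one sample")
    a = np.zeros(bins.n_bins)
    for s in samples:
        a[bins.index(sample_value(s, bins.parameter))] += s.area
    return a / a.sum()


def utilization_curve(
    samples: Sequence[SampleRecord],
    bins: BinScheme,
    standardized: Mapping[str, float],
    group: str | None = None,
) -> np.ndarray:
    """P[E/F]: share of (standardized) abundance per bin (sums to 1)."""
    if not samples:
        raise ValueError("utilization curve needs at least one sample")
    u = np.zeros(bins.n_bins)
    for s in samples:
        u[bins.index(sample_value(s, bins.parameter))] += standardized[s.sample_id]
    total = u.sum()
    if total <= 0:
        who = f" for group {group}" if group else ""
        raise ValueError(f"total abundance is zero{who}; no utilization curve")
    return u / total


def preference_curve(
    huc: np.ndarray, hac: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """P_r = P[E/F] / P[E] with a defined-mask for zero-availability bins.

    Returns ``(hpc, defined)`` where ``hpc`` is NaN outside the mask.  Use
    recorded in a bin with no availability is inconsistent input and raises.
    """
    huc = np.asarray(huc, dtype=float)
    hac = np.asarray(hac, dtype=float)
    if huc.shape != hac.shape:
        raise ValueError("HUC and HAC must share one bin scheme")
    defined = hac > 0
    if (huc[~defined] > 0).any():
        raise ValueError(
            "use recorded in bins with zero availability; utilization and "
            "availability curves are inconsistent"
        )
    hpc = np.full_like(hac, np.nan)
    hpc[defined] = huc[defined] / hac[defined]
    return hpc, defined


def to_si(values: np.ndarray, defined: np.ndarray | None = None) -> np.ndarray:
    """Rescale a curve by its maximum over defined bins to a 0-1 SI.

    Masked (undefined) bins stay NaN.  All-zero curves have no best bin and
    raise.
    """
    values = np.asarray(values, dtype=float)
    if defined is None:
        defined = ~np.isnan(values)
    defined = np.asarray(defined, dtype=bool)
    if not defined.any():
        raise ValueError("no defined bins")
    peak = np.nanmax(values[defined])
    if not peak > 0:
        raise ValueError("all defined values are zero; SI undefined")
    si = np.full_like(values, np.nan)
    si[defined] = values[defined] / peak
    return si


@dataclass(frozen=True)
class ExcessReport:
    """Signed availability-use differences plus diagnostic bin lists.

    ``troughs`` flags bins where availability exceeds use — candidate true
    low-preference troughs (the habitat was on offer but lightly used), the
    check that separates genuinely bimodal preference from unsampled habitat.
    ``use_without_availability`` flags bins carrying use despite near-zero
    availability.
    """

    diff: np.ndarray
    troughs: tuple[int, ...]
    use_without_availability: tuple[int, ...]


def huc_hac_excess(
    hac: np.ndarray,
    huc: np.ndarray,
    atol: float = 1e-12,
    near_zero: float = 1e-9,
) -> ExcessReport:
    """Per-bin signed difference P[E] - P[E/F] with trough diagnostics."""
    hac = np.asarray(hac, dtype=float)
    huc = np.asarray(huc, dtype=float)
    if hac.shape != huc.shape:
        raise ValueError("curves must share one bin scheme")
    diff = hac - huc
    troughs = tuple(int(i) for i in np.nonzero(diff > atol)[0])
    orphan_use = tuple(
        int(i) for i in np.nonzero((hac <= near_zero) & (huc > atol))[0]
    )
    return ExcessReport(diff=diff, troughs=troughs,
                        use_without_availability=orphan_use)


@dataclass(frozen=True)
class CurveSet:
    """All curves for one parameter, one organism group, one campaign scope.

    ``campaign`` is a campaign id or ``"combined"``.  ``hpc`` and ``si_hpc``
    are NaN where ``defined`` is False (no habitat availability in the bin).
    """

    parameter: str
    group: str
    campaign: str
    bins: BinScheme
    hac: np.ndarray
    huc: np.ndarray
    hpc: np.ndarray
    si_huc: np.ndarray
    si_hpc: np.ndarray
    defined: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows: dict[str, object] = {
            "parameter": self.parameter,
            "group": self.group,
            "campaign": self.campaign,
        }
        df = pd.DataFrame(rows, index=range(self.bins.n_bins))
        if self.bins.kind == "continuous":
            df["bin_lo"] = [lo for lo, _ in self.bins.bounds()]
            df["bin_hi"] = [hi for _, hi in self.bins.bounds()]
        else:
            df["category"] = list(self.bins.categories)
        df["hac"] = self.hac
        df["huc"] = self.huc
        df["hpc"] = self.hpc
        df["si_huc"] = self.si_huc
        df["si_hpc"] = self.si_hpc
        df["defined"] = self.defined
        return df


def build_curve_set(
    samples: Iterable[SampleRecord],
    membership: FFGMembership,
    group: str,
    bins: BinScheme,
    campaign: str = "combined",
) -> CurveSet:
    """Assemble HAC, HUC, HPC and their SI vectors for one campaign scope.

    ``campaign="combined"`` pools all samples (abundances still standardized
    within each campaign); a campaign id restricts to that campaign.
    """
    samples = list(samples)
    if campaign != "combined":
        samples = [s for s in samples if s.campaign_id == campaign]
        if not samples:
            raise ValueError(f"no samples in campaign {campaign!r}")
    standardized = standardize_by_campaign(samples, membership, group)
    hac = availability_curve(samples, bins)
    huc = utilization_curve(samples, bins, standardized, group=group)
    hpc, defined = preference_curve(huc, hac)
    si_huc = huc / huc.max()
    si_hpc = to_si(hpc, defined)
    return CurveSet(
        parameter=bins.parameter, group=group, campaign=campaign, bins=bins,
        hac=hac, huc=huc, hpc=hpc, si_huc=si_huc, si_hpc=si_hpc,
        defined=defined,
    )


@dataclass(frozen=True)
class FinalCurve:
    """A final habitat suitability curve (SI per bin) for one group."""

    parameter: str
    group: str
    bins: BinScheme
    si: np.ndarray
    defined: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "group": self.group,
                "bin": list(self.bins.labels()),
                "si": self.si,
            }
        )


def _campaign_si(cs: CurveSet | FinalCurve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(cs, FinalCurve):
        return cs.si, cs.defined
    si = np.full(cs.bins.n_bins, np.nan)
    si[cs.defined] = np.fmax(cs.si_huc[cs.defined], cs.si_hpc[cs.defined])
    return si, cs.defined.copy()


def combine_campaigns(
    curvesets: Sequence[CurveSet | FinalCurve],
    strategy: str = "envelope_fill",
    fill_threshold: float = 0.8,
) -> FinalCurve:
    """Merge per-campaign curves into the final habitat suitability curve.

    ``pointwise_max`` takes, bin by bin, the largest of si_huc and si_hpc
    across campaigns, treating masked bins as absent — the suitability seen
    under *any* sampled flow condition counts.  ``envelope_fill`` (continuous
    parameters only) additionally sets SI = 1 on every bin between the first
    and last bin whose pointwise maximum reaches ``fill_threshold``,
    reproducing the widened SI = 1 plateau that arises when curves from
    different discharges are offset along the parameter axis; the result is
    renormalized to max 1.  Both strategies are idempotent and envelope_fill
    dominates pointwise_max elementwise.
    """
    if not curvesets:
        raise ValueError("need at least one curve set")
    bins = curvesets[0].bins
    for cs in curvesets[1:]:
        if cs.bins != bins:
            raise ValueError("curve sets must share one bin scheme")
    if strategy not in ("pointwise_max", "envelope_fill"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "envelope_fill" and bins.kind != "continuous":
        raise ValueError("envelope_fill is undefined for categorical parameters")

    per = [_campaign_si(cs) for cs in curvesets]
    defined = np.zeros(bins.n_bins, dtype=bool)
    si = np.full(bins.n_bins, np.nan)
    for values, mask in per:
        take = mask & (~defined | (values > np.nan_to_num(si, nan=-1.0)))
        si[take] = values[take]
        defined |= mask

    if strategy == "envelope_fill":
        # normalize to max 1 before thresholding (idempotence requires the
        # threshold to be applied on the final scale); filling can then only
        # add exact 1s, so no post-normalization is needed
        peak = np.nanmax(si[defined])
        if peak > 0:
            si[defined] = si[defined] / peak
        high = np.nonzero(defined & (np.nan_to_num(si, nan=-1.0) >= fill_threshold))[0]
        if high.size:
            lo, hi = int(high[0]), int(high[-1])
            si[lo:hi + 1] = 1.0
            defined[lo:hi + 1] = True

    group = curvesets[0].group
    parameter = curvesets[0].parameter
    return FinalCurve(parameter=parameter, group=group, bins=bins,
                      si=si, defined=defined)
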