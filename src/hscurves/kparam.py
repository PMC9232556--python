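"""The K suitability coefficient: a per-microhabitat composite of community
structure, normalized by the dataset maximum.

For microhabitat i the raw coefficient is the fixed-weight sum

    k_raw(i) = 0.4 n_i + 0.3 H_i + 0.2 EPT_i + 0.1 alpha_i

with n_i the number of macroinvertebrate families present, H_i the Shannon
diversity, EPT_i the number of Ephemeroptera/Plecoptera/Trichoptera
individuals, and alpha_i the density (individuals per m**2).  K_i is
k_raw(i) divided by the maximum over the whole dataset, so the best
microhabitat scores exactly 1.  Components enter unscaled, as published,
even though the density term can dominate numerically; an optional
``normalize_components`` switch divides each component by its dataset
maximum first (off by default).

Note on EPT_i: it counts *individuals*, not taxa, following the coefficient
definition adopted here.  Some related indices use EPT richness instead;
users porting values between studies should check which convention applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .community_stats import ept_count, shannon
from .data_io import SampleRecord, TraitRecord
from .suitability import BinScheme, sample_value

__all__ = [
    "K_WEIGHTS",
    "KRecord",
    "KEnvelope",
    "k_components",
    "k_values",
    "compute_k",
    "k_upper_envelope",
    "krecords_frame",
]

#: Fixed weights applied to (n_i, H_i, EPT_i, alpha_i), in that order.
K_WEIGHTS: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)


@dataclass(frozen=True)
class KRecord:
    """K coefficient of one microhabitat with its four components."""

    sample_id: str
    n_families: int
    shannon: float
    ept: int
    density: float
    k_raw: float
    k: float


@dataclass(frozen=True)
class KEnvelope:
    """Binned upper envelope of K values, optionally compared to an SI curve."""

    parameter: str
    bins: BinScheme
    envelope: np.ndarray
    defined: np.ndarray
    abs_diff: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "parameter": self.parameter,
                "bin": list(self.bins.labels()),
                "k_envelope": self.envelope,
                "defined": self.defined,
            }
        )
        if self.abs_diff is not None:
            df["abs_diff_si_huc"] = self.abs_diff
        return df


def k_components(
    sample: SampleRecord, traits: Iterable[TraitRecord]
) -> tuple[int, float, int, float]:
    """(n_i, H_i, EPT_i, alpha_i) for one microhabitat.

    Family richness counts distinct families with at least one individual;
    an empty microhabitat yields all zeros (Shannon maps to 0 there).
    """
    traits = list(traits)
    families = {t.taxon: t.family for t in traits}
    missing = sorted(t for t in sample.counts if t not in families)
    if missing:
        raise ValueError(f"taxa without trait records: {missing}")
    present = {taxon: c for taxon, c in sample.counts.items() if c > 0}
    n_fam = len({families[t] for t in present})
    h = shannon(present) if present else 0.0
    ept = ept_count(sample, traits)
    alpha = sample.total_count / sample.area
    return n_fam, h, ept, alpha


def k_values(
    components: Sequence[tuple[int, float, int, float]],
    sample_ids: Sequence[str] | None = None,
    normalize_components: bool = False,
) -> list[KRecord]:
    """Weighted sums and dataset-normalized K for a set of component tuples.

    K_max is taken over the whole dataset passed in (combine campaigns before
    calling if they should share one normalization).  When every k_raw is 0
    all K values are 0 and a warning is emitted.
    """
    if not components:
        raise ValueError("need at least one component tuple")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(components))]
    if len(sample_ids) != len(components):
        raise ValueError("sample_ids and components length mismatch")

    comp = np.asarray(components, dtype=float)  # (n, 4)
    scaled = comp.copy()
    if normalize_components:
        maxima = comp.max(axis=0)
        nonzero = maxima > 0
        scaled[:, nonzero] = comp[:, nonzero] / maxima[nonzero]
    k_raw = scaled @ np.asarray(K_WEIGHTS)
    k_max = k_raw.max()
    if k_max > 0:
        k = k_raw / k_max
    else:
        warnings.warn("all k_raw values are zero; K set to 0", stacklevel=2)
        k = np.zeros_like(k_raw)
    return [
        KRecord(
            sample_id=str(sid),
            n_families=int(c[0]),
            shannon=float(c[1]),
            ept=int(c[2]),
            density=float(c[3]),
            k_raw=float(raw),
            k=float(ki),
        )
        for sid, c, raw, ki in zip(sample_ids, comp, k_raw, k)
    ]


def compute_k(
    samples: Sequence[SampleRecord],
    traits: Iterable[TraitRecord],
    normalize_components: bool = False,
) -> list[KRecord]:
    """Convenience wrapper: components then K for every sample."""
    traits = list(traits)
    comps = [k_components(s, traits) for s in samples]
    return k_values(
        comps,
        sample_ids=[s.sample_id for s in samples],
        normalize_components=normalize_components,
    )


def k_upper_envelope(
    krecords: Sequence[KRecord],
    samples: Sequence[SampleRecord],
    bins: BinScheme,
    parameter: str,
    si_huc: np.ndarray | None = None,
) -> KEnvelope:
    """Per-bin maximum K among the microhabitats falling in each bin.

    Empty bins are masked.  When ``si_huc`` is given, the per-bin absolute
    difference |envelope - si_huc| is attached for comparison with the
    utilization curve on the same bins.
    """
    by_id = {r.sample_id: r.k for r in krecords}
    envelope = np.full(bins.n_bins, np.nan)
    defined = np.zeros(bins.n_bins, dtype=bool)
    for s in samples:
        if s.sample_id not in by_id:
            raise ValueError(f"no K record for sample {s.sample_id!r}")
        i = bins.index(sample_value(s, parameter))
        k = by_id[s.sample_id]
        if not defined[i] or k > envelope[i]:
            envelope[i] = k
        defined[i] = True
    abs_diff = None
    if si_huc is not None:
        si_huc = np.asarray(si_huc, dtype=float)
        if si_huc.shape != envelope.shape:
            raise ValueError("si_huc must share the envelope's bin scheme")
        abs_diff = np.abs(envelope - si_huc)
    return KEnvelope(
        parameter=parameter, bins=bins, envelope=envelope,
        defined=defined, abs_diff=abs_diff,
    )


def krecords_frame(records: Sequence[KRecord]) -> pd.DataFrame:
    """Tabular form of K records (one row per microhabitat)."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "n_i": r.n_families,
                "H_i": r.shannon,
                "EPT_i": r.ept,
                "alpha_i": r.density,
                "k_raw": r.k_raw,
                "k": r.k,
            }
            for r in records
        ]
    )
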