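"""Functional feeding group classification and group projection of counts.

A taxon belongs to a feeding guild when its 10-point allocation assigns the
guild at least ``threshold`` points (default 3).  Membership is binary and
may overlap: an opportunistic taxon with, say, 6 gatherer points and 4 grazer
points is a full member of both guilds and contributes its whole abundance to
each.  Parasites (PAR) and the residual "others" (OTH) bucket are excluded
from curve analyses by default; the community group aggregates everything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .data_io import FFG_LABELS, SampleRecord, TraitRecord

__all__ = [
    "COMMUNITY",
    "CURVE_FFGS",
    "FFGMembership",
    "assign_ffg",
    "analysis_groups",
    "project_counts",
]

#: Label of the whole-assemblage pseudo-group.
COMMUNITY = "COMMUNITY"

#: Guilds analysed by default, in presentation order.
CURVE_FFGS: tuple[str, ...] = ("GRA", "SHR", "GAT", "FF", "PRE")


@dataclass(frozen=True)
class FFGMembership:
    """Binary guild membership of every taxon at a given threshold."""

    threshold: int
    members: Mapping[str, frozenset[str]]

    @property
    def unassigned(self) -> tuple[str, ...]:
        """Taxa whose allocation reaches the threshold in no guild.

        Possible when 10 points are spread over four or more guilds (e.g.
        2+2+2+2+2).  Such taxa still count toward the community group.
        """
        return tuple(sorted(t for t, s in self.members.items() if not s))

    def of(self, taxon: str) -> frozenset[str]:
        try:
            return self.members[taxon]
        except KeyError:
            raise ValueError(f"taxon {taxon!r} has no FFG membership record") from None


def assign_ffg(traits: Iterable[TraitRecord], threshold: int = 3) -> FFGMembership:
    """Classify taxa into guilds by thresholding their 10-point allocation.

    Raising the threshold can only shrink membership sets.  Taxa left without
    any guild are reported through a warning (and ``FFGMembership.unassigned``)
    rather than silently dropped.
    """
    if not 1 <= threshold <= 10:
        raise ValueError(f"threshold must be in 1..10, got {threshold}")
    members = {
        t.taxon: frozenset(
            label for label in FFG_LABELS if t.allocation[label] >= threshold
        )
        for t in traits
    }
    result = FFGMembership(threshold=threshold, members=members)
    if result.unassigned:
        warnings.warn(
            "taxa with no FFG membership at threshold "
            f"{threshold}: {list(result.unassigned)}; they contribute only to "
            "the community group",
            stacklevel=2,
        )
    return result


def analysis_groups(
    include: Sequence[str] = (), exclude: Sequence[str] = ()
) -> tuple[str, ...]:
    """Ordered organism groups to build curves for.

    Default: the community plus the five trophic guilds.  Parasites and
    "others" can be opted in through ``include``; any default group can be
    removed through ``exclude``.
    """
    groups = [COMMUNITY, *CURVE_FFGS]
    for label in include:
        if label not in FFG_LABELS:
            raise ValueError(f"unknown FFG label {label!r}")
        if label not in groups:
            groups.append(label)
    return tuple(g for g in groups if g not in set(exclude))


def project_counts(
    sample: SampleRecord, membership: FFGMembership, group: str
) -> int:
    """Abundance of one sample projected onto an organism group.

    The community projection is the total count.  A guild projection sums the
    full counts of member taxa — a taxon in two guilds contributes its whole
    count to both (binary membership, no fractional splitting).
    """
    if group == COMMUNITY:
        return sample.total_count
    if group not in FFG_LABELS:
        raise ValueError(f"unknown group label {group!r}")
    return sum(
        count for taxon, count in sample.counts.items()
        if group in membership.of(taxon)
    )
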