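"""Per-mouse aggregation, normalization and group comparisons.

The migration rate of one mouse is the pooled ratio

    migration_rate = (total melanocytes) / (total hair follicles)

over all of that animal's fields (equivalently the follicle-count-weighted
mean of per-field rates).  Two normalization schemes are supported:
dividing by a per-mouse expression level (e.g. a Cox-2 staining area ratio)
and dividing by the rate of a littermate control animal within the same
experimental group.  Group comparisons are the tests used in the source
experiments: two-tailed Welch t, paired t, and Mann–Whitney U; dispersion
is reported as SEM (sd/sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from enum import Enum

import numpy as np
from scipy import stats as sps

from ._errors import InsufficientDataError, ValidationError
from .wholemount import ImageRecord

__all__ = [
    "NormScheme",
    "TestName",
    "MouseMigration",
    "NormalizedMigration",
    "GroupComparison",
    "aggregate_mouse",
    "normalize_migration",
    "compare_groups",
]

# Per-mouse quantification floor: fewer pooled follicles than this gets a
# warning flag (the study design pools >= 6000 follicles per animal).
MIN_FOLLICLES_PER_MOUSE = 6000


class NormScheme(str, Enum):
    cox2 = "cox2"
    littermate_control = "littermate_control"


class TestName(str, Enum):
    welch_t = "welch_t"
    paired_t = "paired_t"
    mann_whitney = "mann_whitney"


@dataclass
class MouseMigration:
    mouse_id: str
    group: str
    sex: str
    total_follicles: int
    total_mcsc: int
    migration_rate: float
    n_fields: int
    flags: list[str] = dc_field(default_factory=list)


@dataclass
class NormalizedMigration:
    mouse_id: str
    raw_rate: float
    normalizer: float
    normalized_rate: float
    scheme: NormScheme


@dataclass
class GroupComparison:
    test: TestName
    statistic: float
    p_value: float
    group_means: tuple[float, float]
    group_sems: tuple[float, float]
    n: tuple[int, int]
    flags: list[str] = dc_field(default_factory=list)


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def aggregate_mouse(records: list[ImageRecord], group: str = "",
                    sex: str = "") -> MouseMigration:
    """Pool per-field counts into one per-mouse migration rate.

    All records must share a mouse id and the pooled follicle count must be
    positive.  A ``below_follicle_floor`` flag is raised when fewer than
    6000 follicles back the rate.
    """
    if not records:
        raise ValidationError("need at least one field record")
    ids = {r.mouse_id for r in records}
    if len(ids) != 1:
        raise ValidationError(f"records mix mouse ids: {sorted(ids)}")
    total_f = sum(r.n_follicles for r in records)
    total_m = sum(r.n_mcsc for r in records)
    if total_f <= 0:
        raise ValidationError("zero total follicles; migration rate undefined")
    flags = []
    if total_f < MIN_FOLLICLES_PER_MOUSE:
        flags.append("below_follicle_floor")
    return MouseMigration(mouse_id=records[0].mouse_id, group=group, sex=sex,
                          total_follicles=total_f, total_mcsc=total_m,
                          migration_rate=total_m / total_f,
                          n_fields=len(records), flags=flags)


def normalize_migration(raw: MouseMigration, normalizer: float,
                        scheme: NormScheme | str) -> NormalizedMigration:
    """Divide a raw migration rate by a positive per-mouse normalizer.

    ``cox2``: normalizer is the animal's Cox-2 expression level (by default
    the Cox-2 immunofluorescence area ratio from matched sections).
    ``littermate_control``: normalizer is the migration rate of the matched
    control littermate within the same experimental group.
    """
    scheme = NormScheme(scheme)
    if not np.isfinite(normalizer) or normalizer <= 0:
        raise ValidationError("normalizer must be a positive finite number")
    return NormalizedMigration(mouse_id=raw.mouse_id,
                               raw_rate=raw.migration_rate,
                               normalizer=float(normalizer),
                               normalized_rate=raw.migration_rate / normalizer,
                               scheme=scheme)


def compare_groups(a, b, test: TestName | str = TestName.welch_t,
                   paired_ids: tuple[list, list] | None = None) -> GroupComparison:
    """Two-sided group comparison with SEM reporting.

    ``welch_t``: unequal-variance t with Welch–Satterthwaite df.
    ``paired_t``: requires equal sizes; when ``paired_ids`` (two id lists)
    is given, ``b`` is reordered to match ``a``'s ids.  Zero variance of
    the paired differences raises a ``degenerate_variance`` flag (statistic
    and p are NaN) instead of a misleading p-value.
    ``mann_whitney``: exact two-sided p when both groups have n <= 8 and no
    ties, else a tie-corrected normal approximation.
    """
    test = TestName(test)
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each group needs n >= 2")

    if test is TestName.paired_t:
        if paired_ids is not None:
            ia, ib = paired_ids
            if len(ia) != len(x) or len(ib) != len(y):
                raise ValidationError("paired_ids lengths must match the data")
            pos = {pid: j for j, pid in enumerate(ib)}
            if set(ia) != set(ib):
                raise ValidationError("paired_ids do not match between groups")
            y = y[[pos[pid] for pid in ia]]
        if len(x) != len(y):
            raise ValidationError("paired test requires equal group sizes")

    flags: list[str] = []
    if test is TestName.welch_t:
        res = sps.ttest_ind(x, y, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test is TestName.paired_t:
        d = x - y
        if np.std(d, ddof=1) == 0:
            flags.append("degenerate_variance")
            stat, p = float("nan"), float("nan")
        else:
            res = sps.ttest_rel(x, y)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) \
            else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)

    return GroupComparison(test=test, statistic=stat, p_value=p,
                           group_means=(float(np.mean(x)), float(np.mean(y))),
                           group_sems=(_sem(x), _sem(y)),
                           n=(len(x), len(y)), flags=flags)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Optional BH-FDR adjustment (off by default in all pipelines)."""
    p = np.asarray(p_values, dtype=np.float64)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj
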