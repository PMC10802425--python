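"""Centres of mass, angular separations, ANOVA, areas and overlaps.

Angles of group centres of mass across animals are compared with a one-way
fixed-effects ANOVA after unwrapping each group's angles about its circular
mean onto the real line (group circular means are themselves unwrapped
about the pooled circular mean so the 0°/360° seam cannot split a cluster),
followed by Tukey-Kramer pairwise comparisons.  A Watson-Williams circular
test is available behind a flag as a cross-check.

Separation summaries use circular statistics: the mean separation of a
group pair is the folded absolute circular mean of the per-animal signed
CoM differences, and the SD is the circular SD.  This keeps a planted
180° separation unbiased (arithmetic averaging of separations folded to
[0, 180] would shrink it toward the centre).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import (
    GROUPS,
    CircularMap,
    CoM,
    InsufficientDataError,
    OverlapResult,
    SeparationResult,
    ValidationError,
    VagusMapError,
    pixel_centers,
    signed_angle_diff_deg,
    xy_to_angle_deg,
)

log = logging.getLogger(__name__)

GROUP_PAIRS = tuple(itertools.combinations(GROUPS, 2))


class UndefinedCoMError(VagusMapError):
    """The centre of mass of an all-zero map is undefined."""


# ---------------------------------------------------------------------------
# Centres of mass and angular arithmetic

def center_of_mass(cmap: CircularMap) -> CoM:
    """|value|-weighted centroid of pixel centres, in polar form."""
    w = np.abs(cmap.values)
    total = float(w.sum())
    if total == 0.0:
        raise UndefinedCoMError(
            f"map (group={cmap.group!r}, animal={cmap.animal_id!r}) is all zero"
        )
    X, Y = pixel_centers(cmap.grid_size)
    cx = float((w * X).sum() / total)
    cy = float((w * Y).sum() / total)
    return CoM(
        group=cmap.group,
        animal_id=cmap.animal_id,
        angle_deg=float(xy_to_angle_deg(cx, cy)),
        r_norm=float(np.hypot(cx, cy)),
        weight_total=total,
    )


def angular_difference(a_deg: float, b_deg: float) -> float:
    """Unsigned circular difference in [0, 180]."""
    d = abs(a_deg - b_deg) % 360.0
    return float(min(d, 360.0 - d))


def circular_mean_deg(angles_deg) -> float:
    """Circular mean in [0, 360)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.rad2deg(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))) % 360.0)

def circular_sd_deg(angles_deg) -> float:
    """Circular standard deviation sqrt(-2 ln R̄), degrees."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    rbar = float(np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a))))
    rbar = min(rbar, 1.0)
    if rbar == 0.0:
        return float("inf")
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(rbar))))


# ---------------------------------------------------------------------------
# Group separation

def group_separation(
    coms_a: list[CoM],
    coms_b: list[CoM],
    p_value: float | None = None,
) -> SeparationResult:
    """Per-animal angular separation between two groups' CoM angles.

    Animals with a CoM missing in either group are excluded.  ``mean_deg``
    is the folded absolute circular mean of the signed per-animal
    differences and ``sd_deg`` their circular SD; the per-animal list holds
    the folded separations in [0, 180].
    """
    by_a = {c.animal_id: c for c in coms_a}
    by_b = {c.animal_id: c for c in coms_b}
    animals = [aid for aid in by_a if aid in by_b]
    if len(animals) < 2:
        raise InsufficientDataError(
            f"need >= 2 animals with both CoMs defined, have {len(animals)}"
        )
    signed = np.array(
        [
            signed_angle_diff_deg(by_a[a].angle_deg, by_b[a].angle_deg)
            for a in animals
        ],
        dtype=float,
    )
    folded = [float(abs(s)) for s in signed]
    mean_signed = circular_mean_deg(signed)
    mean_deg = angular_difference(mean_signed, 0.0)
    sd_deg = circular_sd_deg(signed)
    ga = coms_a[0].group
    gb = coms_b[0].group
    return SeparationResult(
        group_pair=(ga, gb),
        per_animal_separation_deg=folded,
        mean_deg=mean_deg,
        sd_deg=sd_deg,
        p_value=p_value,
    )


# ---------------------------------------------------------------------------
# ANOVA on angular locations

@dataclass
class AnovaResult:
    """Omnibus and pairwise p-values of the angular-location comparison."""

    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    method: str = "linear"
    unwrapped: dict[str, np.ndarray] = field(default_factory=dict)
    degenerate: bool = False


def _unwrap_groups(angles_by_group: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Map each group's angles to the real line about coherent group means."""
    pooled = circular_mean_deg(np.concatenate(list(angles_by_group.values())))
    out = {}
    for g, a in angles_by_group.items():
        gm = circular_mean_deg(a)
        gm_line = pooled + float(signed_angle_diff_deg(gm, pooled))
        out[g] = gm_line + np.asarray(signed_angle_diff_deg(a, gm), dtype=float)
    return out


def _kappa_est(rbar: float) -> float:
    # Fisher (1993) approximation for the von Mises concentration
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def _watson_williams(groups: list[np.ndarray]) -> float:
    """Watson-Williams high-concentration F-test for equal circular means."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    rads = [np.deg2rad(g) for g in groups]
    resultants = [float(np.hypot(np.sin(a).sum(), np.cos(a).sum())) for a in rads]
    allr = np.concatenate(rads)
    r_all = float(np.hypot(np.sin(allr).sum(), np.cos(allr).sum()))
    rw = sum(resultants)
    denom = n - rw
    if denom <= 0:
        return 0.0
    f = ((n - k) / (k - 1)) * (rw - r_all) / denom
    kappa = _kappa_est(rw / n)
    if kappa > 0:
        f *= 1 + 3 / (8 * kappa)
    return float(sps.f.sf(f, k - 1, n - k))


def angular_anova(
    angles_by_group: dict[str, list[float]],
    method: str = "linear",
    include_pairwise: bool = True,
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way comparison of CoM angular locations across groups.

    ``method='linear'`` (default) unwraps the angles and runs an ordinary
    one-way ANOVA with Tukey-Kramer pairwise comparisons;
    ``method='watson_williams'`` uses the circular F-test (pairwise p-values
    Bonferroni-adjusted).
    """
    groups = {g: np.asarray(a, dtype=float) for g, a in angles_by_group.items()}
    if len(groups) < 2 or any(len(a) < 2 for a in groups.values()):
        raise InsufficientDataError("need >= 2 groups with >= 2 angles each")

    if method == "watson_williams":
        omnibus = _watson_williams(list(groups.values()))
        pairwise = {}
        if include_pairwise:
            pairs = list(itertools.combinations(groups, 2))
            for ga, gb in pairs:
                p = _watson_williams([groups[ga], groups[gb]])
                pairwise[(ga, gb)] = min(1.0, p * len(pairs))
        return AnovaResult(omnibus_p=omnibus, pairwise_p=pairwise, method=method)
    if method != "linear":
        raise ValidationError(f"unknown method {method!r}")

    unwrapped = _unwrap_groups(groups)
    degenerate = all(np.ptp(a) == 0 for a in unwrapped.values())
    if degenerate:
        log.warning("all groups have zero angular variance; F is degenerate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, omnibus = sps.f_oneway(*unwrapped.values())
    pairwise = {}
    if include_pairwise:
        values = np.concatenate(list(unwrapped.values()))
        labels = np.concatenate(
            [np.repeat(g, len(a)) for g, a in unwrapped.items()]
        )
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        # tukeyhsd orders pairs as combinations of the sorted unique labels
        names = list(itertools.combinations(np.unique(labels), 2))
        for (ga, gb), p in zip(names, np.atleast_1d(tk.pvalues)):
            pairwise[(str(ga), str(gb))] = float(p)
    return AnovaResult(
        omnibus_p=float(omnibus),
        pairwise_p=pairwise,
        method="linear",
        unwrapped=unwrapped,
        degenerate=degenerate,
    )


def pairwise_p(anova: AnovaResult, ga: str, gb: str) -> float | None:
    """Adjusted p-value for a group pair, order-insensitive."""
    return anova.pairwise_p.get((ga, gb), anova.pairwise_p.get((gb, ga)))


# ---------------------------------------------------------------------------
# Areas and overlaps

def _region_array(region) -> np.ndarray:
    a = region.values if isinstance(region, CircularMap) else np.asarray(region)
    return a > 0


def area_fraction(region) -> float:
    """Region area as percent of the disk (pixel-count ratio)."""
    r = _region_array(region)
    from .core import disk_mask

    disk = disk_mask(r.shape[0])
    return 100.0 * float((r & disk).sum()) / float(disk.sum())


def overlap(region_a, region_b, group_pair=("A", "B")) -> OverlapResult:
    """Mutual overlap of two binary regions on the same grid.

    Percentages are relative to each region's own area; an empty region's
    overlap percentage is undefined and reported as ``None``.
    """
    a = _region_array(region_a)
    b = _region_array(region_b)
    if a.shape != b.shape:
        raise ValidationError(f"grid mismatch: {a.shape} vs {b.shape}")
    inter = float((a & b).sum())
    na, nb = float(a.sum()), float(b.sum())
    if isinstance(region_a, CircularMap) and isinstance(region_b, CircularMap):
        group_pair = (region_a.group, region_b.group)
    return OverlapResult(
        group_pair=tuple(group_pair),
        area_pct_a=area_fraction(a),
        area_pct_b=area_fraction(b),
        overlap_pct_of_a=100.0 * inter / na if na else None,
        overlap_pct_of_b=100.0 * inter / nb if nb else None,
    )


# ---------------------------------------------------------------------------
# Cohort summary

@dataclass
class CohortReport:
    """Assembled per-technique statistics for one cohort."""

    technique: str
    com_table: pd.DataFrame
    area_table: pd.DataFrame
    separation_table: pd.DataFrame
    overlap_table: pd.DataFrame
    omnibus_p: float

    def to_text(self) -> str:
        lines = [
            f"Cohort summary ({self.technique})",
            "=" * 40,
            f"Omnibus ANOVA of CoM angular locations: p = {self.omnibus_p:.4g}",
            "",
            "Mean area fraction per group (% of cross-section):",
            self.area_table.to_string(index=False),
            "",
            "Pairwise CoM angular separations:",
            self.separation_table.to_string(index=False),
            "",
            "Region overlaps (atlas support):",
            self.overlap_table.to_string(index=False),
            "",
            "Note: alignment pins the cardiac_efferent CoM near 0 degrees, "
            "deflating its between-animal angular variance; separations "
            "involving it inherit that convention.",
        ]
        return "\n".join(lines)

    def to_csv(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        t = self.technique
        self.com_table.to_csv(out / f"{t}_coms.csv", index=False)
        self.area_table.to_csv(out / f"{t}_areas.csv", index=False)
        self.separation_table.to_csv(out / f"{t}_separations.csv", index=False)
        self.overlap_table.to_csv(out / f"{t}_overlaps.csv", index=False)


def summary_report(
    aligned_maps: dict[str, dict[str, CircularMap]],
    technique: str,
    source_kind: str | None = None,
) -> CohortReport:
    """Full statistics table for one cohort of aligned per-animal maps.

    ``aligned_maps`` maps animal_id -> group -> aligned CircularMap.
    Overlaps are computed on thresholded atlas supports (the default
    region definition); areas are per-animal means.
    """
    from .atlas_builder import atlas_support, build_atlas

    if source_kind is None:
        any_map = next(iter(next(iter(aligned_maps.values())).values()))
        source_kind = any_map.kind if any_map.kind in ("binary", "response") else "binary"

    coms: dict[str, list[CoM]] = {g: [] for g in GROUPS}
    areas: dict[str, list[float]] = {g: [] for g in GROUPS}
    for animal, by_group in aligned_maps.items():
        for g in GROUPS:
            m = by_group.get(g)
            if m is None:
                continue
            areas[g].append(area_fraction(np.abs(m.values) > 0))
            try:
                coms[g].append(center_of_mass(m))
            except UndefinedCoMError:
                log.warning("animal %s: group %s CoM undefined (empty map)", animal, g)

    usable = {g: c for g, c in coms.items() if len(c) >= 2}
    angles_by_group = {g: [c.angle_deg for c in cs] for g, cs in usable.items()}
    anova = angular_anova(angles_by_group)

    sep_rows = []
    for ga, gb in GROUP_PAIRS:
        if ga in usable and gb in usable:
            try:
                sep = group_separation(
                    usable[ga], usable[gb], p_value=pairwise_p(anova, ga, gb)
                )
            except InsufficientDataError:
                continue
            sep_rows.append(
                dict(
                    group_a=ga,
                    group_b=gb,
                    n=sep.n,
                    mean_deg=sep.mean_deg,
                    sd_deg=sep.sd_deg,
                    p_adj=sep.p_value,
                )
            )

    atlases = {}
    for g in GROUPS:
        group_maps = [
            by_group[g] for by_group in aligned_maps.values() if g in by_group
        ]
        if group_maps:
            atlases[g] = build_atlas(group_maps, source_kind=source_kind)
    supports = {g: atlas_support(a) for g, a in atlases.items()}

    ov_rows = []
    for ga, gb in GROUP_PAIRS:
        if ga in supports and gb in supports:
            ov = overlap(supports[ga], supports[gb], group_pair=(ga, gb))
            ov_rows.append(
                dict(
                    group_a=ga,
                    group_b=gb,
                    area_pct_a=ov.area_pct_a,
                    area_pct_b=ov.area_pct_b,
                    overlap_pct_of_a=ov.overlap_pct_of_a,
                    overlap_pct_of_b=ov.overlap_pct_of_b,
                )
            )

    com_rows = [
        dict(group=g, animal_id=c.animal_id, angle_deg=c.angle_deg, r_norm=c.r_norm)
        for g, cs in coms.items()
        for c in cs
    ]
    area_rows = [
        dict(group=g, mean_area_pct=float(np.mean(a)), n=len(a))
        for g, a in areas.items()
        if a
    ]
    return CohortReport(
        technique=technique,
        com_table=pd.DataFrame(com_rows),
        area_table=pd.DataFrame(area_rows),
        separation_table=pd.DataFrame(sep_rows),
        overlap_table=pd.DataFrame(ov_rows),
        omnibus_p=anova.omnibus_p,
    )
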