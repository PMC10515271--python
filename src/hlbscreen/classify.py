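"""The screen's decision procedure.

A candidate ChIP/input pair is called POSITIVE only if a peak emerges in
the input-normalized ChIP signal that has no counterpart in the input, and
none of four false-positive signatures is present:

1. gene-body overrepresentation in the input (library/alignment bias);
2. intergenic underrepresentation in the input (same class of bias);
3. ChIP and input coverage that look identical (normalization then
   manufactures peaks out of input structure);
4. a peak over the GA-repeat elements in a dataset with read length
   <= 50 bp (multimapping pileup, not binding).

Rules 1-3 are dataset-level and evaluated on the INPUT track — these
artifacts live in the library and are revealed by the input; the same
scores computed on the ChIP track are reported as diagnostics only. Rule 4
is per-peak. The original criteria are visual; every numeric cutoff here is
a named, overridable config field quantifying them, except the 50 bp read
length bound which the screen states explicitly (inclusive).

Positive peaks are localized to array elements (promoters and genes), the
screen's element-level readout (e.g. a TRF2-like factor at the H1 promoter,
Hox-like factors at the H3/H4 promoter).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .align import CoverageTrack
from .annotation import ArrayAnnotation, intergenic_intervals
from .normalize import (
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_TARGET_TOTAL,
    RatioTrack,
    depth_scale,
    log2_ratio,
    smooth,
)


class ArtifactFlag(str, enum.Enum):
    GENE_BODY_BIAS = "GENE_BODY_BIAS"
    INTERGENIC_DEPLETION = "INTERGENIC_DEPLETION"
    INPUT_IDENTICAL = "INPUT_IDENTICAL"
    GA_ARTIFACT = "GA_ARTIFACT"


@dataclass(frozen=True)
class Peak:
    """A called peak on the circular unit; start/end half-open, may wrap."""

    start: int
    end: int
    summit: int
    max_ratio: float
    mean_ratio: float

    def width(self, unit_length: int) -> int:
        w = (self.end - self.start) % unit_length
        return w if w else unit_length

    def positions(self, unit_length: int) -> np.ndarray:
        return (self.start + np.arange(self.width(unit_length))) % unit_length


@dataclass(frozen=True)
class ClassifierConfig:
    """Quantified thresholds for the screen's qualitative criteria.

    peak_z / min_peak_width define peak calling on the smoothed ratio
    track; input_peak_z defines "present in the input"; the three ratio
    cutoffs quantify "obvious overrepresentation", "underrepresentation"
    and "looked identical"; ga_read_length_max is the screen's inclusive
    50 bp bound. smooth_window (bp, odd) spans one default read length so
    single-position multimapping pileups survive the width filter.
    """

    peak_z: float = 3.0
    min_peak_width: int = 50
    input_peak_z: float = 2.0
    genebody_ratio_max: float = 1.5
    intergenic_ratio_min: float = 0.5
    identity_corr_min: float = 0.95
    ga_read_length_max: int = 50
    smooth_window: int = 75
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    target_total: float = DEFAULT_TARGET_TOTAL


@dataclass
class CandidateCall:
    """The screen verdict for one ChIP/input pair."""

    label: str  # "positive" | "negative"
    emergent_peaks: list[Peak]
    flags: set[ArtifactFlag]
    localization: list[list[str]]  # element names per emergent peak
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label == "positive" and not self.emergent_peaks:
            raise ValueError("a positive call must carry at least one emergent peak")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "flags": sorted(f.value for f in self.flags),
            "peaks": [
                {
                    "start": p.start,
                    "end": p.end,
                    "summit": p.summit,
                    "max_ratio": round(p.max_ratio, 6),
                    "mean_ratio": round(p.mean_ratio, 6),
                    "elements": self.localization[i],
                }
                for i, p in enumerate(self.emergent_peaks)
            ],
            "diagnostics": self.diagnostics,
        }


# -- peak calling ----------------------------------------------------------


def _circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True on a circular mask as (start, length)."""
    L = len(mask)
    if not mask.any():
        return []
    if mask.all():
        return [(0, L)]
    z = int(np.flatnonzero(~mask)[0])
    m = np.roll(mask, -z)
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = list(np.flatnonzero(d == -1) + 1)
    if m[-1]:
        ends.append(L)
    runs = [((int(s) + z) % L, int(e) - int(s)) for s, e in zip(starts, ends)]
    runs.sort()
    return runs


def _call_runs(values: np.ndarray, z: float, min_width: int) -> list[Peak]:
    """Threshold at mean + z*SD and return qualifying circular runs as peaks."""
    L = len(values)
    t = float(values.mean()) + z * float(values.std())
    peaks = []
    for start, length in _circular_runs(values > t):
        if length < min_width:
            continue
        pos = (start + np.arange(length)) % L
        vals = values[pos]
        summit = int(pos[int(np.argmax(vals))])  # leftmost max in run order
        end = start + length
        end = end if end <= L else end - L
        peaks.append(Peak(start, end, summit, float(vals.max()), float(vals.mean())))
    peaks.sort(key=lambda p: p.start)
    return peaks


def call_peaks(ratio: RatioTrack, config: ClassifierConfig = ClassifierConfig()) -> list[Peak]:
    """Peaks on the smoothed ratio track.

    Threshold is mean + peak_z * SD of the smoothed values; peaks are
    maximal circular runs strictly above threshold with width >=
    min_peak_width. A constant track has SD 0 and yields no peaks.
    """
    values = smooth(ratio.values, config.smooth_window)
    return _call_runs(values, config.peak_z, config.min_peak_width)


def emergence_test(
    chip_peaks: list[Peak],
    input_cov: CoverageTrack,
    config: ClassifierConfig = ClassifierConfig(),
) -> list[Peak]:
    """Keep only ChIP peaks with no corresponding input peak.

    A peak is dropped when the depth-scaled, smoothed input coverage over
    the peak interval exceeds the input's own mean + input_peak_z * SD.
    """
    if not chip_peaks:
        return []
    sm = smooth(depth_scale(input_cov, config.target_total), config.smooth_window)
    t = float(sm.mean()) + config.input_peak_z * float(sm.std())
    L = input_cov.unit_length
    return [p for p in chip_peaks if float(sm[p.positions(L)].mean()) <= t]


# -- false-positive rules --------------------------------------------------


def _interior_mask(mask: np.ndarray, margin: int) -> np.ndarray:
    """Erode each maximal run of a circular mask by ``margin`` on both edges.

    Region means computed on coverage are diluted near region boundaries:
    a read starting just inside (or just outside) a region spreads one
    read length of coverage across the edge. Scoring region interiors
    removes that dilution so the score matches the analytic expectation
    from the underlying read-start density. Runs that erosion would empty
    are kept whole.
    """
    if margin <= 0:
        return mask
    out = np.zeros_like(mask)
    for start, length in _circular_runs(mask):
        L = len(mask)
        if length > 2 * margin:
            pos = (start + np.arange(margin, length - margin)) % L
        else:
            pos = (start + np.arange(length)) % L
        out[pos] = True
    return out


def detect_gene_body_bias(
    input_cov: CoverageTrack,
    annotation: ArrayAnnotation,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[float, bool]:
    """Gene-body overrepresentation in the input.

    Score = mean scaled input coverage over gene-body interiors (edges
    eroded by one read length) / mean over all bases; flagged when
    strictly above ``genebody_ratio_max``.
    """
    mask = annotation.mask("gene")
    if not mask.any():
        raise ValueError("annotation has no gene-body bases")
    mask = _interior_mask(mask, input_cov.read_length - 1)
    scaled = depth_scale(input_cov, config.target_total)
    score = float(scaled[mask].mean() / scaled.mean())
    return score, score > config.genebody_ratio_max


def detect_intergenic_depletion(
    input_cov: CoverageTrack,
    annotation: ArrayAnnotation,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[float, bool]:
    """Intergenic underrepresentation in the input.

    Score = mean scaled input coverage over intergenic interiors (edges
    eroded by one read length, as for the gene-body rule) / overall mean;
    flagged when strictly below ``intergenic_ratio_min``. With no
    intergenic bases the rule is not applicable: score NaN, no flag.
    """
    iv = intergenic_intervals(annotation)
    if not iv:
        return float("nan"), False
    mask = _interior_mask(
        ~annotation.mask("gene", "promoter"), input_cov.read_length - 1
    )
    scaled = depth_scale(input_cov, config.target_total)
    score = float(scaled[mask].mean() / scaled.mean())
    return score, score < config.intergenic_ratio_min


def detect_input_identity(
    chip_cov: CoverageTrack,
    input_cov: CoverageTrack,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[float, bool]:
    """ChIP and input coverage "look identical".

    Pearson correlation of the depth-scaled vectors; flagged when the
    correlation exceeds ``identity_corr_min`` AND each track individually
    contains a called peak (two flat tracks correlating is not the
    artifact). Zero-variance tracks give NaN and no flag.
    """
    if chip_cov.unit_length != input_cov.unit_length:
        raise ValueError(
            f"track length mismatch: chip {chip_cov.unit_length} != "
            f"input {input_cov.unit_length}"
        )
    c = depth_scale(chip_cov, config.target_total)
    i = depth_scale(input_cov, config.target_total)
    if c.std() == 0 or i.std() == 0:
        return float("nan"), False
    corr = float(np.corrcoef(c, i)[0, 1])
    if corr <= config.identity_corr_min:
        return corr, False
    both_peaky = all(
        _call_runs(smooth(v, config.smooth_window), config.peak_z, config.min_peak_width)
        for v in (c, i)
    )
    return corr, both_peaky


def detect_ga_artifact(
    peaks: list[Peak],
    annotation: ArrayAnnotation,
    read_length: int,
    config: ClassifierConfig = ClassifierConfig(),
) -> list[Peak]:
    """Subset of peaks that are GA-repeat multimapping artifacts.

    A peak is flagged iff the dataset's read length is <= the (inclusive)
    bound AND the peak overlaps any ga_repeat feature.
    """
    if read_length > config.ga_read_length_max:
        return []
    L = annotation.unit_length
    ga = annotation.by_kind("ga_repeat")
    flagged = []
    for p in peaks:
        pos = p.positions(L)
        if any(((pos >= f.start) & (pos < f.end)).any() for f in ga):
            flagged.append(p)
    return flagged


# -- element localization --------------------------------------------------


def assign_elements(
    peak: Peak, annotation: ArrayAnnotation, min_overlap_frac: float = 0.25
) -> list[str]:
    """Promoter/gene features a peak localizes to.

    A feature qualifies when it overlaps at least ``min_overlap_frac`` of
    the peak width or contains the summit; the summit-containing feature is
    listed first, remaining ones by descending overlap.
    """
    L = annotation.unit_length
    width = peak.width(L)
    pos = peak.positions(L)
    scored = []
    for f in annotation.by_kind("promoter", "gene"):
        ov = int(((pos >= f.start) & (pos < f.end)).sum())
        has_summit = f.contains(peak.summit)
        if has_summit or ov >= min_overlap_frac * width:
            scored.append((not has_summit, -ov, f.start, f.name))
    return [name for *_, name in sorted(scored)]


# -- full procedure --------------------------------------------------------


def classify_candidate(
    chip_cov: CoverageTrack,
    input_cov: CoverageTrack,
    annotation: ArrayAnnotation,
    read_length: int,
    config: ClassifierConfig = ClassifierConfig(),
) -> CandidateCall:
    """ratio -> peaks -> emergence -> GA rule -> dataset-level rules -> label.

    Positive iff at least one emergent peak carries no GA flag and none of
    the three dataset-level flags is set. All diagnostic scores (including
    the bias scores recomputed on the ChIP track) are recorded.
    """
    ratio = log2_ratio(chip_cov, input_cov, config.pseudocount, config.target_total)
    raw_peaks = call_peaks(ratio, config)
    emergent = emergence_test(raw_peaks, input_cov, config)
    # The GA rule inspects ALL called ratio peaks, not just emergent ones:
    # multimapping concentrates GA-derived reads identically in ChIP and
    # input, so the pileup can fail the emergence test yet still mark the
    # dataset as artifact-bearing at short read lengths.
    ga_peaks = detect_ga_artifact(raw_peaks, annotation, read_length, config)
    gb_score, gb_flag = detect_gene_body_bias(input_cov, annotation, config)
    ig_score, ig_flag = detect_intergenic_depletion(input_cov, annotation, config)
    corr, id_flag = detect_input_identity(chip_cov, input_cov, config)
    chip_gb_score, _ = detect_gene_body_bias(chip_cov, annotation, config)
    chip_ig_score, _ = detect_intergenic_depletion(chip_cov, annotation, config)

    flags: set[ArtifactFlag] = set()
    if gb_flag:
        flags.add(ArtifactFlag.GENE_BODY_BIAS)
    if ig_flag:
        flags.add(ArtifactFlag.INTERGENIC_DEPLETION)
    if id_flag:
        flags.add(ArtifactFlag.INPUT_IDENTICAL)
    if ga_peaks:
        flags.add(ArtifactFlag.GA_ARTIFACT)

    dataset_clean = not (gb_flag or ig_flag or id_flag)
    clean_peak = any(p not in ga_peaks for p in emergent)
    label = "positive" if (dataset_clean and clean_peak) else "negative"

    diagnostics = {
        "genebody_score": round(gb_score, 6),
        "intergenic_score": None if np.isnan(ig_score) else round(ig_score, 6),
        "identity_corr": None if np.isnan(corr) else round(corr, 6),
        "chip_genebody_score": round(chip_gb_score, 6),
        "chip_intergenic_score": None if np.isnan(chip_ig_score) else round(chip_ig_score, 6),
        "read_length": read_length,
        "n_raw_peaks": len(raw_peaks),
        "n_emergent_peaks": len(emergent),
        "n_ga_flagged_peaks": len(ga_peaks),
    }
    return CandidateCall(
        label,
        emergent,
        flags,
        [assign_elements(p, annotation) for p in emergent],
        diagnostics,
    )


def classify_replicates(calls: list[CandidateCall]) -> CandidateCall:
    """Conservative replicate combination.

    Positive only when ALL replicates are positive; flags are unioned.
    Localization is the intersection of the per-replicate top peaks'
    element sets (top = highest max_ratio); on an empty intersection the
    union is reported with a disagreement diagnostic.
    """
    if not calls:
        raise ValueError("classify_replicates requires at least one call")
    label = "positive" if all(c.label == "positive" for c in calls) else "negative"
    flags = set().union(*(c.flags for c in calls))

    top_sets = []
    top_peaks = []
    for c in calls:
        if c.emergent_peaks:
            i = max(range(len(c.emergent_peaks)), key=lambda j: c.emergent_peaks[j].max_ratio)
            top_peaks.append(c.emergent_peaks[i])
            top_sets.append(set(c.localization[i]))
    disagreement = False
    if top_sets:
        inter = set.intersection(*top_sets)
        if inter:
            elements = sorted(inter)
        else:
            elements = sorted(set.union(*top_sets))
            disagreement = bool(len(top_sets) > 1)
    else:
        elements = []
    diagnostics = {
        "n_replicates": len(calls),
        "replicate_labels": [c.label for c in calls],
        "combined_elements": elements,
        "localization_disagreement": disagreement,
        "replicates": [c.to_dict() for c in calls],
    }
    if label == "positive":
        call = CandidateCall(label, top_peaks, flags, [elements] + [[] for _ in top_peaks[1:]], diagnostics)
    else:
        call = CandidateCall("negative", top_peaks, flags,
                             [elements] + [[] for _ in top_peaks[1:]] if top_peaks else [],
                             diagnostics)
    return call
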