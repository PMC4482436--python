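"""Mean-intensity atlas construction and registration evaluation.

A reference image is chosen from the population; every other image is
registered to it and resampled into the reference space.  The atlas
intensity image is the voxel-wise arithmetic mean of the registered set
(reference included, so a population of one is well defined) and the atlas
label image is the reference segmentation.  Registration quality is scored
by the Dice similarity coefficient per structure, and methods are compared
with paired two-sided Wilcoxon signed-rank tests on corresponding DSCs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .registration import RegistrationConfig, RegistrationResult, register
from .transforms import CombinedTransform, identity_transform
from .volume import LabelVolume, Volume, resample


@dataclass
class Atlas:
    intensity: Volume
    labels: LabelVolume
    provenance: list = field(default_factory=list)  # (identifier, CombinedTransform)


def dice(a: LabelVolume, b: LabelVolume, label) -> float:
    """Dice similarity 2|A&B| / (|A|+|B|) for one label; 0 = no overlap,
    1 = perfect agreement; both-empty defined as 0 with a warning."""
    if a.data.shape != b.data.shape:
        raise ValueError("dice requires volumes on the same grid")
    ma = a.mask(label)
    mb = b.mask(label)
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        warnings.warn(f"dice of two empty masks for label {label!r} defined as 0")
        return 0.0
    return 2.0 * int((ma & mb).sum()) / denom


def wilcoxon_two_sided(x, y):
    """Paired two-sided Wilcoxon signed-rank test on corresponding values.

    Zero differences are dropped (wilcox convention); the exact null
    distribution is used for n <= 25.  All-zero differences degenerate to
    p = 1 with a warning.  Returns (statistic, p_value).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = y - x
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    if len(nz) < 5:
        warnings.warn(f"only {len(nz)} nonzero differences; test has little power")
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(x, y, alternative="two-sided", zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)


def evaluate_registration(fixed_seg: LabelVolume, moving_seg: LabelVolume,
                          t: CombinedTransform | None = None) -> pd.DataFrame:
    """Per-structure Dice of the moving segmentation warped into fixed space.

    The moving labels are resampled with nearest-neighbour interpolation
    through ``t`` (identity if None, i.e. the unregistered baseline) and
    compared against the fixed manual labels.  Rows cover the structures
    present in both inputs; structures missing from one side are marked
    absent (NaN dice).
    """
    t = t if t is not None else identity_transform()
    warped = resample(moving_seg, t, fixed_seg)
    code_to_name = {v: k for k, v in fixed_seg.labels.items()}
    rows = []
    all_codes = sorted(set(fixed_seg.present_labels()) | set(moving_seg.present_labels()))
    for code in all_codes:
        name = code_to_name.get(code, str(code))
        in_f = bool(fixed_seg.mask(code).any())
        in_m = bool(moving_seg.mask(code).any())
        if in_f and in_m:
            rows.append((name, code, dice(fixed_seg, warped, code)))
        else:
            rows.append((name, code, np.nan))
    return pd.DataFrame(rows, columns=["structure", "label", "dice"])


def build_atlas(reference: Volume, reference_labels: LabelVolume,
                others: list, cfg: RegistrationConfig | None = None,
                other_segs: list | None = None,
                identifiers: list | None = None) -> Atlas:
    """Register each other image to the reference and average.

    ``others`` are moving images; when the shape penalty is enabled their
    segmentations must be supplied in ``other_segs``.  A failed
    registration excludes that subject with a warning.  The mean includes
    the reference itself.
    """
    if not others:
        raise ValueError("build_atlas needs at least one other image")
    cfg = cfg or RegistrationConfig()
    identifiers = identifiers or [f"subject_{i}" for i in range(len(others))]
    acc = reference.data.astype(np.float64).copy()
    count = 1
    provenance = [("reference", identity_transform())]
    for i, mov in enumerate(others):
        seg = other_segs[i] if other_segs else None
        try:
            res: RegistrationResult = register(reference, mov,
                                               fixed_seg=reference_labels,
                                               moving_seg=seg, cfg=cfg)
        except Exception as exc:  # noqa: BLE001 - any subject failure is skipped
            warnings.warn(f"registration of {identifiers[i]} failed ({exc}); excluded")
            continue
        warped = resample(mov, res.transform, reference)
        acc += warped.data
        count += 1
        provenance.append((identifiers[i], res.transform))
    mean = Volume(acc / count, reference.spacing.copy(), reference.origin.copy())
    labels = LabelVolume(reference_labels.data.copy(), reference_labels.spacing.copy(),
                         reference_labels.origin.copy(), labels=dict(reference_labels.labels))
    return Atlas(intensity=mean, labels=labels, provenance=provenance)


def mean_atlas_of_registered(reference: Volume, registered: list) -> Volume:
    """Arithmetic mean of already-registered volumes plus the reference."""
    acc = reference.data.astype(np.float64).copy()
    for vol in registered:
        if not vol.same_grid(reference):
            raise ValueError("registered volumes must share the reference grid")
        acc += vol.data
    return Volume(acc / (1 + len(registered)), reference.spacing.copy(), reference.origin.copy())
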