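"""Synthetic volumetric cohorts with planted, graded disease signal.

The generator emulates the structure of a skull-stripped, intensity-normalized
T1 brain-MRI study of Alzheimer's disease at desk scale:

* a toy **parcellation** — contiguous axis-aligned blocks tiling the interior
  of the grid, surrounded by a one-voxel background shell (label 0), standing
  in for an anatomical atlas;
* three diagnostic classes — NC (normal cognition), MCI (mild cognitive
  impairment) and AD (dementia due to Alzheimer's disease) — with class
  imbalance allowed (NC > MCI > AD in realistic cohorts);
* per-subject, per-region ordinal severity grades g in {0,1,2,3}
  (none / mild / moderate / severe), drawn from class-ordered categorical
  distributions: NC concentrated at 0, MCI intermediate, AD concentrated at
  2-3;
* "atrophy" planted as additive intensity attenuation: inside each designated
  disease region r the volume loses ``effect_size * g_r`` of intensity before
  Gaussian noise and clipping to [0, 1].

Everything is reproducible bitwise from ``CohortSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Parcellation",
    "VolumeSample",
    "CohortSpec",
    "CLASS_NAMES",
    "STAINS",
    "GRADE_PROBS",
    "make_parcellation",
    "generate_cohort",
    "grade_signal_consistency",
    "stain_grade_table",
]

CLASS_NAMES = ("NC", "MCI", "AD")
STAINS = ("amyloid_beta", "NFT", "NP")

#: Categorical distributions over grades {0,1,2,3}, one per class.
#: NC is concentrated at none, AD at moderate/severe; the nonzero mass at
#: grade 0 for MCI doubles as partial region coverage (an MCI subject
#: typically has some unaffected disease regions).
GRADE_PROBS = {
    0: (0.85, 0.15, 0.00, 0.00),  # NC
    1: (0.25, 0.40, 0.25, 0.10),  # MCI
    2: (0.00, 0.10, 0.35, 0.55),  # AD
}

# Base field intensity range inside the brain mask. Leaving headroom below
# 0.4 keeps attenuation (<= 3 * effect_size) clipping-free for the default
# effect sizes, so grade -> signal stays exactly linear.
_BASE_LO, _BASE_HI = 0.40, 0.90


@dataclass
class Parcellation:
    """Integer label grid: 0 = background shell, 1..R = named regions."""

    labels: np.ndarray
    region_names: dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        ids = np.unique(self.labels)
        ids = ids[ids != 0]
        expected = np.arange(1, len(self.region_names) + 1)
        if not np.array_equal(np.sort(ids), expected):
            raise ValueError("every region id in 1..R must own at least one voxel")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def region_ids(self) -> list[int]:
        return sorted(self.region_names)


@dataclass
class VolumeSample:
    """One subject: scaled volume, diagnosis, and optional ground truth.

    ``base`` and ``attenuation`` are generator-side ground truth (the noise-
    and disease-free field and the planted signal) kept for validation; real
    data has no analogue of them.
    """

    volume: np.ndarray
    label: int
    subject_id: str
    grades: dict[int, int] | None = None
    cohort: str = "synthetic"
    base: np.ndarray | None = field(default=None, repr=False)
    attenuation: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.label not in (0, 1, 2):
            raise ValueError("label must be 0 (NC), 1 (MCI) or 2 (AD)")
        if self.grades is not None:
            bad = {g for g in self.grades.values() if g not in (0, 1, 2, 3)}
            if bad:
                raise ValueError(f"grades must lie in {{0..3}}, got {sorted(bad)}")


@dataclass(frozen=True)
class CohortSpec:
    """Generative study conditions for one synthetic cohort."""

    n_per_class: tuple[int, int, int]
    shape: tuple[int, int, int]
    n_regions: int
    disease_regions: frozenset[int]
    effect_size: float
    noise_sd: float
    seed: int

    def __post_init__(self):
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be non-negative")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be >= 0")
        if not set(self.disease_regions) <= set(range(1, self.n_regions + 1)):
            raise ValueError("disease_regions must be a subset of 1..n_regions")


def _balanced_factorization(n: int) -> tuple[int, int, int]:
    """Split n into three factors as close to cubic as possible."""
    best = None
    for a in range(1, n + 1):
        if n % a:
            continue
        m = n // a
        for b in range(1, m + 1):
            if m % b:
                continue
            c = m // b
            dims = tuple(sorted((a, b, c)))
            score = dims[2] - dims[0]
            if best is None or score < best[0]:
                best = (score, dims)
    return best[1]


def _random_cuts(rng: np.random.Generator, length: int, parts: int) -> list[slice]:
    """Partition range(length) into `parts` contiguous nonempty chunks.

    Cut points sit at the even-split positions plus a small seeded jitter,
    so region volumes stay comparable (anatomical regions differ in size,
    but not by orders of magnitude).
    """
    if parts > length:
        raise ValueError(f"cannot cut a length-{length} axis into {parts} nonempty parts")
    even = np.arange(1, parts) * length / parts
    max_jitter = length / (4.0 * parts)
    cuts = np.round(even + rng.uniform(-max_jitter, max_jitter, size=parts - 1)).astype(int)
    cuts = np.clip(cuts, np.arange(1, parts), length - np.arange(parts - 1, 0, -1))
    cuts = np.maximum.accumulate(cuts)  # keep ordering after clipping
    for i in range(1, len(cuts)):  # enforce nonempty chunks
        if cuts[i] <= cuts[i - 1]:
            cuts[i] = cuts[i - 1] + 1
    bounds = np.concatenate([[0], cuts, [length]])
    return [slice(int(bounds[i]), int(bounds[i + 1])) for i in range(parts)]


def make_parcellation(shape: tuple[int, int, int], n_regions: int, seed: int = 0) -> Parcellation:
    """Tile the interior of ``shape`` into ``n_regions`` axis-aligned blocks.

    A one-voxel background shell (label 0) surrounds the regions, mirroring
    the empty space around a skull-stripped brain. Cut positions are drawn
    from ``seed``, so two calls with identical arguments are identical.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if any(s < 4 for s in shape):
        raise ValueError("each axis must have at least 4 voxels")
    parts = _balanced_factorization(n_regions)
    interior = tuple(s - 2 for s in shape)
    # assign the largest factor to the largest interior axis
    order = np.argsort(interior)
    parts_sorted = sorted(parts)
    parts_by_axis = [0, 0, 0]
    for rank, ax in enumerate(order):
        parts_by_axis[ax] = parts_sorted[rank]
    for ax in range(3):
        if parts_by_axis[ax] > interior[ax]:
            raise ValueError(
                f"shape {shape} too small: axis {ax} interior {interior[ax]} "
                f"cannot host {parts_by_axis[ax]} blocks"
            )
    rng = np.random.default_rng(seed)
    axis_slices = [_random_cuts(rng, interior[ax], parts_by_axis[ax]) for ax in range(3)]
    labels = np.zeros(shape, dtype=np.int32)
    rid = 0
    for sa in axis_slices[0]:
        for sb in axis_slices[1]:
            for sc in axis_slices[2]:
                rid += 1
                labels[1 + sa.start:1 + sa.stop, 1 + sb.start:1 + sb.stop, 1 + sc.start:1 + sc.stop] = rid
    names = {r: f"region_{r:02d}" for r in range(1, n_regions + 1)}
    return Parcellation(labels, names)


def generate_cohort(spec: CohortSpec, parcellation: Parcellation,
                    cohort: str = "synthetic") -> tuple[list[VolumeSample], np.ndarray]:
    """Draw a full cohort and return ``(samples, effect_map)``.

    ``effect_map`` is the boolean grid of ground-truth disease voxels (the
    union of the designated disease regions). Each subject gets a fresh
    smooth base field, per-region grades from its class's distribution,
    additive attenuation ``effect_size * g_r`` inside region r, Gaussian
    noise inside the brain mask, then clipping to [0, 1].
    """
    if tuple(parcellation.shape) != tuple(spec.shape):
        raise ValueError(f"parcellation shape {parcellation.shape} != spec shape {spec.shape}")
    if parcellation.n_regions != spec.n_regions:
        raise ValueError("parcellation and spec disagree on the number of regions")
    if not spec.disease_regions:
        raise ValueError("disease_regions must be nonempty")
    rng = np.random.default_rng(spec.seed)
    mask = parcellation.labels > 0
    disease = sorted(spec.disease_regions)
    effect_map = np.isin(parcellation.labels, disease)
    region_voxels = {r: parcellation.labels == r for r in disease}
    samples: list[VolumeSample] = []
    for cls, n in enumerate(spec.n_per_class):
        probs = np.array(GRADE_PROBS[cls])
        for i in range(n):
            grades = {r: int(rng.choice(4, p=probs)) for r in disease}
            base = gaussian_filter(rng.standard_normal(spec.shape), sigma=2.0)
            lo, hi = base[mask].min(), base[mask].max()
            base = np.where(mask, _BASE_LO + (_BASE_HI - _BASE_LO) * (base - lo) / (hi - lo), 0.0)
            attenuation = np.zeros(spec.shape)
            for r, g in grades.items():
                attenuation[region_voxels[r]] = spec.effect_size * g
            vol = base - attenuation
            if spec.noise_sd > 0:
                vol = vol + np.where(mask, rng.normal(0.0, spec.noise_sd, spec.shape), 0.0)
            vol = np.clip(vol, 0.0, 1.0)
            samples.append(VolumeSample(
                volume=vol,
                label=cls,
                subject_id=f"sub-{CLASS_NAMES[cls]}{i:03d}",
                grades=grades,
                cohort=cohort,
                base=base,
                attenuation=attenuation,
            ))
    return samples, effect_map


def grade_signal_consistency(sample: VolumeSample, parcellation: Parcellation) -> dict[int, float]:
    """Realized attenuation per graded region, from the generator ground truth.

    For a sample generated with ``noise_sd=0`` (and effect sizes small enough
    that clipping never engages, which holds whenever 3 * effect_size <= 0.4,
    the base-field floor), the realized attenuation of region r equals
    ``effect_size * g_r`` exactly.
    """
    if sample.base is None:
        raise ValueError("sample carries no generator ground truth (base field)")
    if sample.grades is None:
        raise ValueError("sample carries no grades")
    out: dict[int, float] = {}
    for r in sorted(sample.grades):
        vox = parcellation.labels == r
        out[r] = float(np.mean(sample.base[vox] - sample.volume[vox]))
    return out


def stain_grade_table(samples: Iterable[VolumeSample], seed: int = 0):
    """Per-subject, per-region grades for three synthetic stains.

    The amyloid-beta grade is the planted severity itself; the NFT and NP
    grades are the planted severity plus a small ordinal jitter (one level
    down / same / up with probabilities 0.15 / 0.70 / 0.15), clipped to
    {0..3} — three noisy reads of the same underlying pathology, as in a
    multi-stain autopsy assessment.

    Returns a pandas DataFrame with columns
    ``subject_id, region_id, stain, grade``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for s in samples:
        if s.grades is None:
            continue
        for r, g in sorted(s.grades.items()):
            for stain in STAINS:
                if stain == "amyloid_beta":
                    gg = g
                else:
                    gg = int(np.clip(g + rng.choice([-1, 0, 1], p=[0.15, 0.70, 0.15]), 0, 3))
                rows.append({"subject_id": s.subject_id, "region_id": r, "stain": stain, "grade": gg})
    return pd.DataFrame(rows, columns=["subject_id", "region_id", "stain", "grade"])
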