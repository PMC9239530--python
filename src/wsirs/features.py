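"""WSI-level image features and the eight-variable regression input.

From the ten tiles with the highest tumor cell count, each slide yields
32 image features: per tile the tumor cell number, TIL number and tumor
cell percentage (10 x 3), plus the TIL number variance V and the
aggregated nuclear grade G computed over the ten tiles collectively.

Nuclear grading is rule-based: the ratio r of a tumor nucleus area to a
reference TIL nucleus area (304.7 px^2, averaged from representative
TILs) maps to grade 1 (r < 2.5), grade 2 (2.5 <= r <= 3.5) or grade 3
(r > 3.5). Per-cell grades aggregate by a 10% cascade from grade 3 down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .wsi import TileStats

TIL_REF_AREA = 304.7  # px^2, reference TIL nucleus area at 40x

#: the eight regression variables, in model order: the five Magee
#: equation-2 variables followed by the three image features
MODEL_FEATURES = [
    "nottingham",
    "er_h",
    "pr_h",
    "her2_equivocal",
    "tumor_size_cm",
    "densest_tile_tumor_count",
    "til_variance",
    "nuclear_grade",
]

MAGEE2_FEATURES = MODEL_FEATURES[:5]
IMAGE_FEATURES = MODEL_FEATURES[5:]


def compute_h_score(percentage: float, intensity: int) -> float:
    """Immunohistochemistry H-score = staining percentage x intensity.

    Percentage in [0, 100], intensity in {0, 1, 2, 3}; range 0-300.
    """
    if not 0 <= percentage <= 100:
        raise ValueError(f"staining percentage {percentage} outside [0, 100]")
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"staining intensity {intensity} not in {{0, 1, 2, 3}}")
    return percentage * intensity


def til_number_variance(counts: Sequence[float]) -> float:
    """Sample variance of TIL counts over the selected tiles.

    V = sum_i (n_i - nbar)^2 / (m - 1) over the m selected tiles
    (m = 10 normally; the m-1 divisor generalizes to short slides).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("TIL number variance needs at least two tiles")
    return float(np.var(counts, ddof=1))


def cell_nuclear_grade(nucleus_area: float, til_ref_area: float = TIL_REF_AREA) -> int:
    """Grade one tumor nucleus by its area ratio to the TIL reference.

    r < 2.5 -> 1 (ratios below 1 clamp to grade 1), 2.5 <= r <= 3.5 -> 2,
    r > 3.5 -> 3. The middle bin is closed at both ends; grade 3 is
    strictly above 3.5.
    """
    if nucleus_area <= 0:
        raise ValueError("nucleus area must be positive")
    r = nucleus_area / til_ref_area
    eps = 1e-9  # keep areas specified *at* a boundary in the closed middle bin
    if r > 3.5 + eps:
        return 3
    if r >= 2.5 - eps:
        return 2
    return 1


def aggregate_nuclear_grade(grades: Iterable[int]) -> int:
    """Aggregate per-cell grades to a slide grade by the 10% cascade.

    Grade 3 if >= 10% of tumor cells are grade 3; else grade 2 if >= 10%
    are grade 2; else grade 1. With three levels the cascade always
    terminates (the largest fraction is >= 1/3 > 10%).
    """
    grades = np.asarray(list(grades), dtype=int)
    if grades.size == 0:
        raise ValueError("cannot aggregate an empty grade list")
    n = grades.size
    if (grades == 3).sum() / n >= 0.10:
        return 3
    if (grades == 2).sum() / n >= 0.10:
        return 2
    return 1


@dataclass(frozen=True)
class ImageFeatureSet:
    """The per-slide image features.

    ``tile_triplets`` holds (tumor count, TIL count, tumor percentage) in
    top-tile order i = 1..k; flattened together with the TIL number
    variance and the aggregated nuclear grade this gives 32 features for
    the usual k = 10.
    """

    tile_triplets: list[tuple[int, int, float]]
    til_variance: float
    nuclear_grade: int
    short: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.til_variance < 0:
            raise ValueError("TIL number variance cannot be negative")
        if self.nuclear_grade not in (1, 2, 3):
            raise ValueError("aggregated nuclear grade must be 1, 2 or 3")

    @property
    def densest_tile_tumor_count(self) -> int:
        return self.tile_triplets[0][0]

    def flatten(self) -> np.ndarray:
        """Flat feature vector: k triplets, then V, then G (length 3k+2)."""
        flat = [v for trip in self.tile_triplets for v in trip]
        flat += [self.til_variance, float(self.nuclear_grade)]
        return np.asarray(flat, dtype=float)

    def feature_names(self) -> list[str]:
        names = []
        for i in range(len(self.tile_triplets)):
            names += [f"t{i + 1:02d}_tumor", f"t{i + 1:02d}_til", f"t{i + 1:02d}_pct"]
        return names + ["til_var", "nuc_grade"]

    def summary(self) -> pd.Series:
        """The three slide-level variables entering the regression."""
        return pd.Series(
            {
                "densest_tile_tumor_count": self.densest_tile_tumor_count,
                "til_variance": self.til_variance,
                "nuclear_grade": self.nuclear_grade,
            }
        )


def build_image_feature_vector(
    top_stats: Sequence[TileStats],
    tumor_areas: Sequence[float],
    til_ref_area: float = TIL_REF_AREA,
) -> ImageFeatureSet:
    """Assemble the slide's image features from its top tiles.

    ``top_stats`` must be in select_top_tiles order; ``tumor_areas`` pools
    the nucleus areas of tumor cells from those tiles. The nuclear grades
    of the pooled cells aggregate to the slide grade; V is the sample
    variance of the tiles' TIL counts.
    """
    if len(top_stats) < 2:
        raise ValueError("need at least two top tiles")
    if len(tumor_areas) == 0:
        raise ValueError("no tumor nucleus areas pooled from the top tiles")
    triplets = [(s.n_tumor, s.n_til, s.tumor_pct) for s in top_stats]
    v = til_number_variance([s.n_til for s in top_stats])
    grades = [cell_nuclear_grade(a, til_ref_area) for a in tumor_areas]
    g = aggregate_nuclear_grade(grades)
    return ImageFeatureSet(
        tile_triplets=triplets, til_variance=v, nuclear_grade=g,
        short=len(top_stats) < 10,
    )


def extract_slide_features(scene, tile_size: int | None = None, k: int = 10,
                           mask=None, til_ref_area: float = TIL_REF_AREA) -> ImageFeatureSet:
    """Full per-slide feature extraction: tile, select top-k, featurize.

    ``scene`` is a SceneGroundTruth-like object (cells + canvas dims) in
    the 40x frame; ``mask`` an optional tissue mask raster.
    """
    from . import wsi

    ts = tile_size or wsi.DEFAULT_TILE_SIZE
    grid = wsi.build_tile_grid(scene.canvas_width, scene.canvas_height,
                               mask=mask, tile_size=ts)
    assignment = wsi.assign_cells_to_tiles(scene.cells, grid)
    selection = wsi.select_top_tiles(wsi.tissue_stats(assignment.stats, grid), k=k)
    top = wsi.stats_for_tiles(assignment.stats, selection.tile_ids)
    chosen = set(selection.tile_ids)
    areas = [
        c.area
        for c in scene.cells
        if c.cell_class == "tumor" and c.area is not None
        and (int(c.y // ts), int(c.x // ts)) in chosen
    ]
    return build_image_feature_vector(top, areas, til_ref_area=til_ref_area)


@dataclass
class MageeFeatures:
    """The five Magee equation-2 variables.

    ``nottingham`` is either the grade (1-3) or the score (3-9); which one
    is recorded in ``nottingham_mode``. HER2 is dummy-coded: 1 for
    equivocal, 0 for negative.
    """

    nottingham: float
    er_h: float
    pr_h: float
    her2_equivocal: int
    tumor_size_cm: float
    nottingham_mode: str = "grade"

    def __post_init__(self) -> None:
        if isinstance(self.her2_equivocal, str):
            key = self.her2_equivocal.strip().lower()
            mapping = {"negative": 0, "equivocal": 1}
            if key not in mapping:
                raise ValueError(f"unknown HER2 status {self.her2_equivocal!r}")
            self.her2_equivocal = mapping[key]
        if self.her2_equivocal not in (0, 1):
            raise ValueError("her2_equivocal must be binary")
        for name in ("er_h", "pr_h"):
            v = getattr(self, name)
            if not 0 <= v <= 300:
                raise ValueError(f"{name}={v} outside the H-score range [0, 300]")
        if self.tumor_size_cm <= 0:
            raise ValueError("tumor size must be positive")
        if self.nottingham_mode not in ("grade", "score"):
            raise ValueError("nottingham_mode must be 'grade' or 'score'")


@dataclass
class PatientRecord:
    """One patient: Magee variables, image features, RS and metadata."""

    patient_id: str
    magee: MageeFeatures
    image: ImageFeatureSet | Mapping[str, float]
    rs: int
    age: float
    chemo_received: bool | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.rs <= 100:
            raise ValueError("RS must lie in [0, 100]")

    def image_summary(self) -> pd.Series:
        if isinstance(self.image, ImageFeatureSet):
            return self.image.summary()
        return pd.Series({k: self.image[k] for k in IMAGE_FEATURES})


def assemble_model_features(patient) -> pd.Series:
    """Ordered eight-variable vector for one patient.

    Accepts a PatientRecord or any mapping/Series carrying the eight
    MODEL_FEATURES columns. Raises listing every missing variable.
    """
    if isinstance(patient, PatientRecord):
        m = patient.magee
        values = {
            "nottingham": m.nottingham,
            "er_h": m.er_h,
            "pr_h": m.pr_h,
            "her2_equivocal": m.her2_equivocal,
            "tumor_size_cm": m.tumor_size_cm,
            **patient.image_summary().to_dict(),
        }
    else:
        values = dict(patient)
        if "her2_equivocal" in values and isinstance(values["her2_equivocal"], str):
            values["her2_equivocal"] = (
                1 if values["her2_equivocal"].strip().lower() == "equivocal" else 0
            )
    missing = [f for f in MODEL_FEATURES if f not in values or pd.isna(values[f])]
    if missing:
        raise ValueError(f"missing model variables: {', '.join(missing)}")
    return pd.Series({f: float(values[f]) for f in MODEL_FEATURES})


def model_matrix(cohort: pd.DataFrame, features: Sequence[str] = MODEL_FEATURES) -> pd.DataFrame:
    """Feature matrix for a cohort table (one row per patient)."""
    missing = [f for f in features if f not in cohort.columns]
    if missing:
        raise ValueError(f"missing model variables: {', '.join(missing)}")
    return cohort.loc[:, list(features)].astype(float)


def feature_correlation_matrix(
    cohort: pd.DataFrame, features: Sequence[str] = MODEL_FEATURES
) -> pd.DataFrame:
    """Pair-wise absolute Pearson correlations between features."""
    x = model_matrix(cohort, features)
    if len(x) < 3:
        raise ValueError("need at least three patients for correlations")
    constant = [f for f in features if x[f].nunique() <= 1]
    if constant:
        raise ValueError(f"constant features have undefined correlation: {constant}")
    corr = x.corr(method="pearson").abs()
    np.fill_diagonal(corr.values, 1.0)
    return corr
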