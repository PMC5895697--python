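"""Mood dimensionality reduction and diurnal mood profiles.

Six momentary mood items (anxious, elated, sad, angry, irritable,
energetic; Likert 0–6) are reduced by PCA fitted once on entries pooled
across all participants and groups.  The first three components are kept
and oriented deterministically so they read as *negative* mood (sad +
anxious + angry load positively), *positive* mood (elated + energetic) and
*irritability* (irritable).  Scores are interpolable to the 1-min grid and
averaged into minute-of-day diurnal profiles per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from rhythmkit.synthetic import MINUTES_PER_DAY, MOOD_ITEMS

__all__ = [
    "MoodComponentModel",
    "DiurnalMoodProfile",
    "COMPONENT_LABELS",
    "fit_mood_pca",
    "project_mood",
    "average_diurnal_profile",
]

COMPONENT_LABELS = ("negative", "positive", "irritable")

# items whose summed loading fixes each component's sign
_ORIENT_ITEMS = {
    "negative": ("sad", "anxious", "angry"),
    "positive": ("elated", "energetic"),
    "irritable": ("irritable",),
}


@dataclass
class MoodComponentModel:
    """Fitted, oriented 3-component PCA of the six mood items.

    ``loadings`` is items x components (6 x 3); ``item_scales`` is all ones
    when ``standardize=False`` (covariance PCA).  ``orientation_flipped``
    records which raw PCA axes were sign-flipped to satisfy the labelling
    convention.
    """

    loadings: np.ndarray
    item_means: np.ndarray
    item_scales: np.ndarray
    explained_variance: np.ndarray
    standardized: bool
    component_labels: tuple[str, str, str] = COMPONENT_LABELS
    orientation_flipped: tuple[bool, bool, bool] = (False, False, False)

    def to_dict(self) -> dict:
        return {
            "component_labels": list(self.component_labels),
            "items": list(MOOD_ITEMS),
            "loadings": self.loadings.tolist(),
            "item_means": self.item_means.tolist(),
            "item_scales": self.item_scales.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "standardized": self.standardized,
            "orientation_flipped": list(self.orientation_flipped),
        }


@dataclass
class DiurnalMoodProfile:
    """Minute-of-day mean curve for one component in one group, with a
    standard-error band (sd / sqrt(group size)) and a mask of minutes
    outside the prompt window (where values are interpolation-only)."""

    component: str
    group: str
    minutes: np.ndarray
    mean: np.ndarray
    band: np.ndarray
    no_prompt_mask: np.ndarray
    n_participants: int = 0


def _validate_items(frame: pd.DataFrame) -> np.ndarray:
    missing = [c for c in MOOD_ITEMS if c not in frame.columns]
    if missing:
        raise ValueError(f"mood entries missing items: {missing}")
    x = frame.loc[:, list(MOOD_ITEMS)].to_numpy(dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x < 0) or np.any(x > 6):
        raise ValueError("mood items must be finite and within [0, 6]")
    return x


def fit_mood_pca(
    pooled_entries: pd.DataFrame, standardize: bool = True, min_entries: int = 10
) -> MoodComponentModel:
    """PCA on pooled mood entries from all participants and groups.

    Items are centered and (by default) scaled to unit variance —
    correlation-matrix PCA; the items share a 0–6 scale, so covariance PCA
    (``standardize=False``) is also offered.  The first three components
    are retained, ordered by explained variance, and sign-oriented per the
    labelling convention.  A constant item is an error naming the item.
    """
    x = _validate_items(pooled_entries)
    if len(x) < min_entries:
        raise ValueError(f"need at least {min_entries} pooled entries, got {len(x)}")
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1)
    for item, s in zip(MOOD_ITEMS, scales):
        if s == 0.0:
            raise ValueError(f"mood item {item!r} is constant across pooled entries")
    if not standardize:
        scales = np.ones_like(scales)
    z = (x - means) / scales
    pca = PCA(n_components=3, svd_solver="full")
    pca.fit(z)
    loadings = pca.components_.T.copy()  # items x components
    flipped = []
    for k, label in enumerate(COMPONENT_LABELS):
        idx = [MOOD_ITEMS.index(i) for i in _ORIENT_ITEMS[label]]
        flip = loadings[idx, k].sum() < 0
        if flip:
            loadings[:, k] *= -1.0
        flipped.append(bool(flip))
    return MoodComponentModel(
        loadings=loadings,
        item_means=means,
        item_scales=scales,
        explained_variance=pca.explained_variance_.copy(),
        standardized=standardize,
        orientation_flipped=tuple(flipped),
    )


def project_mood(entries: pd.DataFrame, model: MoodComponentModel) -> pd.DataFrame:
    """Score entries on the three oriented components.

    Returns a frame with ``t_min`` (if present in the input) and one column
    per component label.
    """
    x = _validate_items(entries)
    z = (x - model.item_means) / model.item_scales
    scores = z @ model.loadings
    out = pd.DataFrame(scores, columns=list(model.component_labels))
    if "t_min" in entries.columns:
        out.insert(0, "t_min", entries["t_min"].to_numpy())
    return out


def average_diurnal_profile(
    series_by_participant: dict[str, tuple[np.ndarray, np.ndarray]],
    component: str = "",
    group: str = "",
    prompt_window: tuple[float, float] = (10.0, 20.0),
) -> DiurnalMoodProfile:
    """Minute-of-day average of interpolated component series over all
    participant-days in a group.

    ``series_by_participant`` maps participant id to ``(t_min, values)`` on
    the 1-min grid (as produced by mood interpolation).  The dispersion
    band is the per-minute standard deviation across all contributing
    participant-day samples divided by sqrt(group size); the mask flags
    minutes of day outside the prompt window, where the curve rests on the
    overnight linear bridge rather than on ratings.
    """
    if not series_by_participant:
        raise ValueError("average_diurnal_profile requires a non-empty group")
    minutes = np.arange(MINUTES_PER_DAY)
    sums = np.zeros(MINUTES_PER_DAY)
    sqsums = np.zeros(MINUTES_PER_DAY)
    counts = np.zeros(MINUTES_PER_DAY, dtype=int)
    for t_min, values in series_by_participant.values():
        mod = np.asarray(t_min) % MINUTES_PER_DAY
        ok = np.isfinite(values)
        np.add.at(sums, mod[ok], np.asarray(values)[ok])
        np.add.at(sqsums, mod[ok], np.asarray(values)[ok] ** 2)
        np.add.at(counts, mod[ok], 1)
    n_participants = len(series_by_participant)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(
            counts > 1,
            (sqsums - counts * mean**2) / np.maximum(counts - 1, 1),
            0.0,
        )
    band = np.sqrt(np.maximum(var, 0.0)) / np.sqrt(n_participants)
    lo, hi = prompt_window
    hours = minutes / 60.0
    no_prompt = (hours < lo) | (hours > hi)
    return DiurnalMoodProfile(
        component=component,
        group=group,
        minutes=minutes,
        mean=mean,
        band=band,
        no_prompt_mask=no_prompt,
        n_participants=n_participants,
    )
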