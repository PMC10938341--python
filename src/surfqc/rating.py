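"""Rating sessions and score aggregation.

Categorical per-image ratings (good=1, minor_error=2, visible_motion=3,
bad=4) are averaged across a participant's images to a per-rater score, then
across raters to the final continuous quality score in [1, 4] (higher =
worse). "Bad" outranks "visible motion" because a small amount of motion may
leave the reconstruction usable while a bad reconstruction does not.

Deliberation times (ms per rated image) are summarized per rater after an
outlier pass at >5 median absolute deviations, which strips the long pauses a
rater accrues by stepping away mid-session.
"""

from __future__ import annotations

import os
import time
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateInputError,
    EmptyInputError,
    VocabularyError,
)
from .fs_io import RATING_CATEGORIES, RATINGS_COLUMNS, validate_ratings, write_ratings
from .snapshot import SnapshotManifest

#: fixed categorical -> numeric mapping of the 1-4 scale
CATEGORY_VALUES: dict[str, int] = {
    "good": 1,
    "minor_error": 2,
    "visible_motion": 3,
    "bad": 4,
}

_KEYMAP = {"1": "good", "2": "minor_error", "3": "visible_motion", "4": "bad"}


def category_to_numeric(label: str) -> int:
    """Map a rating category to its numeric value on the 1-4 scale."""
    try:
        return CATEGORY_VALUES[label]
    except KeyError:
        raise VocabularyError(
            f"unknown rating category {label!r}; allowed: {RATING_CATEGORIES}"
        ) from None


@dataclass
class ParticipantScore:
    """Per-participant quality score: per-rater means and their combined mean."""

    subject_id: str
    per_rater: dict[str, float]
    combined: float
    n_images: int
    n_raters: int


def score_participant(categories: Iterable[str]) -> float:
    """Arithmetic mean of the numeric ratings of one subject by one rater."""
    values = [category_to_numeric(c) for c in categories]
    if not values:
        raise EmptyInputError("no ratings supplied")
    return float(np.mean(values))


def combine_raters(per_rater_means: Iterable[float]) -> float:
    """Unweighted mean over raters; a single rater passes through unchanged."""
    means = list(per_rater_means)
    if not means:
        raise EmptyInputError("no rater means supplied")
    return float(np.mean(means))


def score_table(
    ratings: pd.DataFrame | Iterable[pd.DataFrame],
    manifest: SnapshotManifest,
) -> pd.DataFrame:
    """Aggregate one or more rating sessions into per-participant scores.

    Returns a frame with one row per subject: per-rater mean columns
    (``score_<rater>``), the combined ``fsqc`` score, ``n_images`` (max per
    rater) and ``n_raters``.
    """
    if isinstance(ratings, pd.DataFrame):
        frames = [ratings]
    else:
        frames = list(ratings)
    allr = validate_ratings(pd.concat(frames, ignore_index=True))
    hash_to_subject = dict(zip(manifest.rows["image_hash"], manifest.rows["subject_id"]))
    unknown = set(allr["image_hash"]) - set(hash_to_subject)
    if unknown:
        raise AlignmentError(f"{len(unknown)} rated image hashes not in manifest")
    allr = allr.assign(
        subject_id=allr["image_hash"].map(hash_to_subject),
        value=allr["category"].map(CATEGORY_VALUES),
    )
    per = (
        allr.groupby(["subject_id", "rater_id"])
        .agg(mean=("value", "mean"), n=("value", "size"))
        .reset_index()
    )
    wide = per.pivot(index="subject_id", columns="rater_id", values="mean")
    out = pd.DataFrame(index=wide.index)
    for rater in wide.columns:
        out[f"score_{rater}"] = wide[rater]
    out["fsqc"] = wide.mean(axis=1, skipna=True)
    out["n_raters"] = wide.notna().sum(axis=1)
    out["n_images"] = per.groupby("subject_id")["n"].max()
    return out.reset_index()


def per_image_worst(ratings: pd.DataFrame, manifest: SnapshotManifest) -> pd.DataFrame:
    """Per-subject worst single-image rating across raters.

    Exported so users can exclude participants on individual image criteria
    (e.g. drop anyone with any image rated 'bad') rather than on the mean.
    """
    allr = validate_ratings(ratings).assign(
        subject_id=lambda d: d["image_hash"].map(
            dict(zip(manifest.rows["image_hash"], manifest.rows["subject_id"]))
        ),
        value=lambda d: d["category"].map(CATEGORY_VALUES),
    )
    worst = allr.groupby("subject_id")["value"].max().rename("worst_image_rating")
    return worst.reset_index()


# ---------------------------------------------------------------------------
# Deliberation times
# ---------------------------------------------------------------------------


def _mad_filter(times_s: np.ndarray, outlier_mad: float) -> np.ndarray:
    """Keep times within outlier_mad MADs of the rater's median.

    MAD = 0 (>= 50% identical times) would make the rule vacuous or remove
    everything, so the filter then falls back to removing only times above
    outlier_mad x median.
    """
    med = np.median(times_s)
    mad = np.median(np.abs(times_s - med))
    if mad > 0:
        keep = np.abs(times_s - med) <= outlier_mad * mad
    else:
        keep = times_s <= outlier_mad * med
    return keep


@dataclass
class DeliberationSummary:
    per_rater: pd.DataFrame  # rater_id, median_s, n_images, n_removed
    median_s: float  # median of per-rater medians
    range_s: tuple[float, float]  # (min, max) across raters


def deliberation_summary(
    ratings: pd.DataFrame,
    manifest: SnapshotManifest,
    outlier_mad: float = 5.0,
) -> DeliberationSummary:
    """Representative per-participant rating time per rater, in seconds.

    Per rater: drop times more than ``outlier_mad`` MADs from that rater's
    median (over all of their image times), take the median over images
    within each participant, then the median over participants. The summary
    reports each rater's number plus the across-rater median and range.
    """
    allr = validate_ratings(ratings)
    hash_to_subject = dict(zip(manifest.rows["image_hash"], manifest.rows["subject_id"]))
    allr = allr.assign(subject_id=allr["image_hash"].map(hash_to_subject))
    rows = []
    for rater, grp in allr.groupby("rater_id"):
        t = grp["deliberation_ms"].to_numpy(float) / 1000.0
        keep = _mad_filter(t, outlier_mad)
        if not keep.any():
            raise DegenerateInputError(f"all deliberation times removed for rater {rater!r}")
        kept = grp.loc[keep]
        per_subject = kept.groupby("subject_id")["deliberation_ms"].median() / 1000.0
        rows.append(
            {
                "rater_id": rater,
                "median_s": float(per_subject.median()),
                "n_images": int(len(t)),
                "n_removed": int((~keep).sum()),
            }
        )
    per_rater = pd.DataFrame(rows)
    meds = per_rater["median_s"].to_numpy()
    return DeliberationSummary(
        per_rater=per_rater,
        median_s=float(np.median(meds)),
        range_s=(float(meds.min()), float(meds.max())),
    )


# ---------------------------------------------------------------------------
# Local rating session
# ---------------------------------------------------------------------------


def run_rating_session(
    manifest: SnapshotManifest,
    rater_id: str,
    images_dir: str | os.PathLike,
    out_path: str | os.PathLike,
    resume: bool = False,
    rerate: Iterable[str] = (),
    input_fn: Callable[[str], str] = input,
    display_fn: Callable[[str], None] | None = None,
    clock: Callable[[], float] = time.monotonic,
) -> pd.DataFrame:
    """Run a terminal rating session over the anonymized images.

    Images are presented in shuffle order; one keystroke (1-4) records the
    category and the wall-clock deliberation time per image. With
    ``resume=True`` images already in ``out_path`` are skipped; hashes listed in ``rerate``
    are asked again and the earlier row is overwritten with the latest rating
    (logged). Missing
    image files are skipped and logged. ``input_fn`` / ``display_fn`` /
    ``clock`` exist for scripted (non-interactive) sessions and tests.
    """
    if display_fn is None:
        display_fn = lambda msg: print(msg)  # noqa: E731
    done: dict[str, dict] = {}
    if resume and os.path.exists(out_path):
        prev = pd.read_csv(out_path, dtype={"image_hash": str, "rater_id": str})
        for _, r in prev.iterrows():
            done[r["image_hash"]] = r.to_dict()
    rerate_set = set(rerate)
    order = manifest.rows.sort_values("shuffle_position")
    for _, row in order.iterrows():
        h = row["image_hash"]
        if h in done and h not in rerate_set:
            continue
        img_path = os.path.join(os.fspath(images_dir), h + ".png")
        if not os.path.exists(img_path):
            display_fn(f"[skip] missing image file {img_path}")
            continue
        display_fn(f"image {h} -> {img_path}")
        t0 = clock()
        while True:
            key = input_fn("rate [1=good 2=minor_error 3=visible_motion 4=bad]: ").strip()
            if key in _KEYMAP:
                break
            display_fn(f"unrecognized key {key!r}")
        elapsed_ms = max((clock() - t0) * 1000.0, 0.0)
        if h in done:
            display_fn(f"[overwrite] re-rated {h}")
        done[h] = {
            "image_hash": h,
            "rater_id": rater_id,
            "category": _KEYMAP[key],
            "deliberation_ms": elapsed_ms,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
    table = pd.DataFrame(list(done.values()), columns=list(RATINGS_COLUMNS))
    write_ratings(table, out_path)
    return table
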