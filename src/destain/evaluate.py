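"""Scoring detection/tracking/classification output against ground truth.

These helpers match detected objects to simulated ones by optimal
one-to-one assignment within a match radius, and are used by the test
suite and the acceptance script to turn pipeline output into recall,
precision and localization-error numbers.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

_UNMATCHABLE = 1e9


def match_points(detected: np.ndarray, truth: np.ndarray,
                 radius_px: float = 2.0) -> dict:
    """One-to-one match of detected (n, 2) to true (m, 2) positions.

    Uses optimal assignment with pairs beyond ``radius_px`` forbidden.
    Returns recall, precision, rmse (over matched pairs, in px) and the
    matched index pairs.
    """
    detected = np.atleast_2d(np.asarray(detected, float))
    truth = np.atleast_2d(np.asarray(truth, float))
    if detected.size == 0 or truth.size == 0:
        return dict(recall=0.0 if truth.size else 1.0,
                    precision=0.0 if detected.size else 1.0,
                    rmse_px=np.nan, n_matched=0, pairs=[])
    d = np.hypot(detected[:, 0][:, None] - truth[:, 0][None, :],
                 detected[:, 1][:, None] - truth[:, 1][None, :])
    cost = np.where(d <= radius_px, d, _UNMATCHABLE)
    ri, ci = linear_sum_assignment(cost)
    ok = cost[ri, ci] < _UNMATCHABLE
    pairs = list(zip(ri[ok], ci[ok]))
    errs = d[ri[ok], ci[ok]]
    n_matched = len(pairs)
    return dict(recall=n_matched / len(truth),
                precision=n_matched / len(detected),
                rmse_px=float(np.sqrt(np.mean(errs ** 2))) if n_matched else np.nan,
                n_matched=n_matched, pairs=pairs)


def score_spot_detection(spots, boutons, drift, radius_px: float = 2.0,
                         drift_corrected: bool = True,
                         trafficking=None) -> dict:
    """Frame-by-frame detection scores against simulated object positions.

    ``spots`` is a detection table with a ``frame`` column; ``boutons``
    the ground-truth bouton table; ``drift`` the simulated per-frame
    (dx, dy).  When the movie was drift-corrected before detection the
    true bouton positions are the frame-0 centres; otherwise they are
    shifted by the drift.  When the ground-truth ``trafficking`` table
    is given, its per-frame positions count as true objects too (they
    are real fluorescent puncta; rejecting them is the tracker's job,
    not the detector's).
    """
    truth0 = boutons[["x_px", "y_px"]].to_numpy(float)
    recalls, precisions, sq_err_sum, total_matched = [], [], 0.0, 0
    for f, grp in spots.groupby("frame"):
        det = grp[["x_px", "y_px"]].to_numpy(float)
        truth = truth0 if drift_corrected else truth0 + drift[int(f)]
        if trafficking is not None:
            tr = trafficking[trafficking["frame"] == int(f)]
            pos = tr[["x_px", "y_px"]].to_numpy(float)
            if drift_corrected and len(pos):
                pos = pos - drift[int(f)]  # trafficking truth is recorded drifted
            if len(pos):
                truth = np.vstack([truth, pos])
        m = match_points(det, truth, radius_px)
        recalls.append(m["recall"])
        precisions.append(m["precision"])
        if m["n_matched"]:
            sq_err_sum += m["rmse_px"] ** 2 * m["n_matched"]
            total_matched += m["n_matched"]
    rmse = float(np.sqrt(sq_err_sum / total_matched)) if total_matched else np.nan
    return dict(recall=float(np.mean(recalls)) if recalls else 0.0,
                precision=float(np.mean(precisions)) if precisions else 0.0,
                rmse_px=rmse, n_frames=spots["frame"].nunique(),
                n_matched=total_matched)


def match_tracks_to_boutons(tracks, boutons, radius_px: float = 2.0) -> dict:
    """How many simulated boutons are recovered by exactly one stationary track.

    A track claims the nearest bouton within ``radius_px`` of its median
    position.  Returns the fraction of boutons with exactly one
    stationary claimant and the per-bouton claim counts.
    """
    truth = boutons[["x_px", "y_px"]].to_numpy(float)
    claims = np.zeros(len(truth), int)
    if len(truth):
        tree = cKDTree(truth)
        for tr in tracks:
            if tr.motion_class != "stationary":
                continue
            pos = (float(np.median(tr.x_px)), float(np.median(tr.y_px)))
            dist, idx = tree.query(pos)
            if dist <= radius_px:
                claims[idx] += 1
    frac = float(np.mean(claims == 1)) if len(truth) else 1.0
    return dict(single_track_fraction=frac, claims=claims)
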