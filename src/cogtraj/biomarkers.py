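"""Reference-anchored biomarker Z-scoring and positivity calls.

All non-amyloid biomarkers are expressed as Z-scores relative to a reference
subset of cognitively unimpaired (CU), amyloid-PET-negative participants
(global PiB DVR <= 1.16, using each participant's last available measure):

* simple Z: (observed - reference mean) / reference SD, used for the tau PET
  composites and plasma pTau217;
* head-size-adjusted Z for the MRI measures (hippocampal volume, global
  brain atrophy, WMH volume): the biomarker is regressed on total
  intracranial volume (TICV = GM + WM + CSF) within the reference subset and
  the Z-score is (observed - predicted) / RMSE, with RMSE on residual
  degrees of freedom (n - 2).

Positivity is called two ways: a fixed cut-off of |Z| > 1.5 in the
modality's pathological direction (primary), and a two-component Gaussian
mixture on each Z-score with the 0.5-posterior crossing as the cut-point
(secondary).  Amyloid positivity itself is DVR > 1.16 (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture

__all__ = [
    "ReferenceStats",
    "ReferenceZScorer",
    "MODALITY_DIRECTIONS",
    "TICV_ADJUSTED",
    "build_reference_subset",
    "fit_reference_stats",
    "zscore_simple",
    "zscore_ticv_adjusted",
    "gba_ratio",
    "amyloid_positive",
    "threshold_positive",
    "gmm_positivity",
]

#: pathological direction per modality (hippocampal volume shrinks with
#: neurodegeneration; every other modality rises).
MODALITY_DIRECTIONS = {
    "tau_mtl": "higher_is_abnormal",
    "tau_mtc": "higher_is_abnormal",
    "ptau217": "higher_is_abnormal",
    "hv": "lower_is_abnormal",
    "gba": "higher_is_abnormal",
    "wmhv": "higher_is_abnormal",
}

#: modalities whose reference model regresses out head size.
TICV_ADJUSTED = frozenset({"hv", "gba", "wmhv"})

DVR_CUTOFF = 1.16
Z_CUTOFF = 1.5


@dataclass(frozen=True)
class ReferenceStats:
    """Reference-subset statistics for one modality."""

    modality: str
    kind: str  # "simple" | "ticv_adjusted"
    n_reference: int
    mean: float | None = None
    sd: float | None = None
    intercept: float | None = None
    slope_ticv: float | None = None
    rmse: float | None = None


def gba_ratio(gm, wm, csf):
    """Global brain atrophy: CSF / (GM + WM), scale-invariant."""
    gm = np.asarray(gm, dtype=float)
    wm = np.asarray(wm, dtype=float)
    csf = np.asarray(csf, dtype=float)
    denom = gm + wm
    if np.any(denom <= 0):
        raise ValueError("GM + WM must be > 0")
    out = csf / denom
    return out if out.ndim else float(out)


def amyloid_positive(dvr, cutoff: float = DVR_CUTOFF):
    """Amyloid PET positivity: DVR strictly greater than the cut-off."""
    dvr = np.asarray(dvr, dtype=float)
    out = dvr > cutoff
    return out if out.ndim else bool(out)


def threshold_positive(z, direction: str, cutoff: float = Z_CUTOFF):
    """Fixed-threshold positivity with strict inequalities."""
    z = np.asarray(z, dtype=float)
    if direction == "higher_is_abnormal":
        out = z > cutoff
    elif direction == "lower_is_abnormal":
        out = z < -cutoff
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return out if out.ndim else bool(out)


def build_reference_subset(
    panel: pd.DataFrame, dvr_cutoff: float = DVR_CUTOFF
) -> pd.DataFrame:
    """CU, amyloid-negative reference rows (last value per participant).

    Keeps, per participant, the last available row (by ``assessment_age``
    when present, ties broken by record order, else plain record order),
    then retains rows that are cognitively unimpaired with DVR <= cutoff.
    """
    req = {"participant_id", "dvr", "cu_flag"}
    missing = req - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns {sorted(missing)}")
    df = panel.reset_index(drop=True)
    if "assessment_age" in df.columns:
        df = df.assign(_order=np.arange(len(df))).sort_values(
            ["assessment_age", "_order"], kind="stable"
        )
    last = df.groupby("participant_id", sort=False).tail(1)
    if "_order" in last.columns:
        last = last.drop(columns="_order")
    ref = last[
        last["cu_flag"].astype(bool) & (last["dvr"] <= dvr_cutoff)
    ].reset_index(drop=True)
    if ref.empty:
        raise ValueError("reference subset (CU, amyloid-negative) is empty")
    return ref


def fit_reference_stats(
    reference: pd.DataFrame, modality: str, kind: str | None = None
) -> ReferenceStats:
    """Reference mean/SD (simple) or OLS-on-TICV fit (ticv_adjusted)."""
    if kind is None:
        kind = "ticv_adjusted" if modality in TICV_ADJUSTED else "simple"
    vals = reference[modality].to_numpy(dtype=float)
    keep = np.isfinite(vals)
    if kind == "simple":
        v = vals[keep]
        if v.size < 2:
            raise ValueError(f"{modality}: need >= 2 reference values")
        return ReferenceStats(
            modality, "simple", int(v.size), mean=float(v.mean()), sd=float(v.std(ddof=1))
        )
    if kind != "ticv_adjusted":
        raise ValueError(f"unknown reference kind {kind!r}")
    ticv = reference["ticv"].to_numpy(dtype=float)
    keep &= np.isfinite(ticv)
    v, t = vals[keep], ticv[keep]
    if v.size < 3:
        raise ValueError(f"{modality}: need >= 3 reference values for regression")
    X = np.column_stack([np.ones_like(t), t])
    coef, _, _, _ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ coef
    rmse = float(np.sqrt((resid**2).sum() / (v.size - 2)))
    return ReferenceStats(
        modality,
        "ticv_adjusted",
        int(v.size),
        intercept=float(coef[0]),
        slope_ticv=float(coef[1]),
        rmse=rmse,
    )


def zscore_simple(value, ref: ReferenceStats):
    if ref.kind != "simple":
        raise ValueError("reference stats are not of kind 'simple'")
    if ref.sd == 0:
        raise ValueError(f"{ref.modality}: zero reference SD")
    value = np.asarray(value, dtype=float)
    out = (value - ref.mean) / ref.sd
    return out if out.ndim else float(out)


def zscore_ticv_adjusted(value, ticv, ref: ReferenceStats):
    if ref.kind != "ticv_adjusted":
        raise ValueError("reference stats are not of kind 'ticv_adjusted'")
    if ref.rmse == 0:
        raise ValueError(f"{ref.modality}: zero reference RMSE")
    value = np.asarray(value, dtype=float)
    ticv = np.asarray(ticv, dtype=float)
    pred = ref.intercept + ref.slope_ticv * ticv
    out = (value - pred) / ref.rmse
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Gaussian-mixture positivity
# ---------------------------------------------------------------------------


def gmm_positivity(z, direction: str, seed=None, n_init: int = 10):
    """Two-component normal-mixture positivity on a Z-score vector.

    Fits an unequal-variance two-component mixture (EM with ``n_init``
    seeded restarts); the abnormal component is the one whose mean lies
    further in the pathological direction.  The cut-point is the Z at which
    the abnormal component's posterior membership crosses 0.5 (the crossing
    nearest the component-mean midpoint); flags are posterior >= 0.5.

    Returns (cutoff, flags, info dict).
    """
    if direction not in ("higher_is_abnormal", "lower_is_abnormal"):
        raise ValueError(f"unknown direction {direction!r}")
    z = np.asarray(z, dtype=float)
    if z.size < 20 or not np.all(np.isfinite(z)):
        raise ValueError("gmm_positivity needs >= 20 finite values")
    zz = z.reshape(-1, 1)
    rs = int(np.random.default_rng(seed).integers(2**31 - 1))
    common = dict(
        n_components=2, covariance_type="full", max_iter=2000, tol=1e-6,
        random_state=rs,
    )
    # EM on a strongly unbalanced mixture has attractive poor local optima;
    # combine random restarts, a k-means start and fully specified
    # tail-quantile starts, keeping the highest-likelihood converged fit
    hi = direction == "higher_is_abnormal"
    q1, q2 = (0.9, 0.975) if hi else (0.1, 0.025)
    s_rob = max((np.quantile(z, 0.75) - np.quantile(z, 0.25)) / 1.349, 1e-6)
    prec = 1.0 / s_rob**2
    candidates = [
        GaussianMixture(n_init=n_init, init_params="random_from_data", **common),
        GaussianMixture(n_init=1, init_params="kmeans", **common),
    ]
    for w_abn, q in ((0.15, q1), (0.05, q2)):
        candidates.append(
            GaussianMixture(
                n_init=1,
                weights_init=np.array([1 - w_abn, w_abn]),
                means_init=np.array([[np.quantile(z, 0.45)], [np.quantile(z, q)]]),
                precisions_init=np.array([[[prec]], [[4.0 * prec]]]),
                **common,
            )
        )
    fits = [c.fit(zz) for c in candidates]
    fits = [f for f in fits if f.converged_]
    if not fits:
        raise RuntimeError("EM did not converge after restarts")
    gm = max(fits, key=lambda f: f.score(zz))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    abn = int(np.argmax(means)) if direction == "higher_is_abnormal" else int(
        np.argmin(means)
    )
    post = gm.predict_proba(zz)
    post_abn = post[:, abn]
    flags = post_abn >= 0.5

    # Ashman's D < 2 indicates the two components do not produce a bimodal
    # density (degenerate single-mode data); the cut-off is then unstable
    sep = np.sqrt(2.0) * abs(means[0] - means[1]) / np.sqrt((sds**2).sum())
    if sep < 2.0:
        warnings.warn(
            f"GMM components poorly separated (Ashman D = {sep:.2f} < 2); "
            "cut-off may be unstable"
        )

    def g(x):
        return gm.predict_proba(np.array([[x]]))[0, abn] - 0.5

    lo = float(z.min() - 3 * sds.max())
    hi = float(z.max() + 3 * sds.max())
    grid = np.linspace(lo, hi, 2001)
    vals = gm.predict_proba(grid.reshape(-1, 1))[:, abn] - 0.5
    crossings = []
    for i in np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:])):
        try:
            crossings.append(brentq(g, grid[i], grid[i + 1]))
        except ValueError:
            pass
    mid = float(means.mean())
    cutoff = (
        min(crossings, key=lambda c: abs(c - mid)) if crossings else mid
    )
    info = {
        "means": means,
        "sds": sds,
        "weights": gm.weights_.ravel(),
        "abnormal_component": abn,
        "separation": sep,
    }
    return float(cutoff), flags, info


# ---------------------------------------------------------------------------
# estimator front end
# ---------------------------------------------------------------------------


class ReferenceZScorer(BaseEstimator, TransformerMixin):
    """Fit reference statistics on a biomarker panel; transform to Z-scores.

    ``fit`` builds the CU/amyloid-negative reference subset (computing the
    GBA ratio from tissue volumes when absent) and fits per-modality
    reference statistics.  ``transform`` returns a long table with one row
    per (participant, modality): raw value, Z-score, primary fixed-threshold
    positivity and, when ``gmm=True``, secondary GMM positivity.

    Parameters: ``dvr_cutoff`` (amyloid positivity threshold on DVR),
    ``z_cutoff`` (fixed Z threshold), ``modalities`` (subset to score),
    ``gmm`` + ``seed`` (secondary calls).
    """

    def __init__(
        self,
        dvr_cutoff: float = DVR_CUTOFF,
        z_cutoff: float = Z_CUTOFF,
        modalities: tuple | None = None,
        gmm: bool = False,
        seed: int | None = None,
    ):
        self.dvr_cutoff = dvr_cutoff
        self.z_cutoff = z_cutoff
        self.modalities = modalities
        self.gmm = gmm
        self.seed = seed

    @staticmethod
    def _with_gba(panel: pd.DataFrame) -> pd.DataFrame:
        df = panel.copy()
        if "gba" not in df.columns and {"gm", "wm", "csf"} <= set(df.columns):
            ok = df[["gm", "wm", "csf"]].notna().all(axis=1)
            df["gba"] = np.nan
            df.loc[ok, "gba"] = gba_ratio(
                df.loc[ok, "gm"], df.loc[ok, "wm"], df.loc[ok, "csf"]
            )
        if "ticv" not in df.columns and {"gm", "wm", "csf"} <= set(df.columns):
            df["ticv"] = df[["gm", "wm", "csf"]].sum(axis=1, min_count=3)
        return df

    def fit(self, X: pd.DataFrame, y=None):
        panel = self._with_gba(X)
        mods = tuple(
            m for m in (self.modalities or MODALITY_DIRECTIONS) if m in panel.columns
        )
        if not mods:
            raise ValueError("no scoreable modalities found in panel")
        ref = build_reference_subset(panel, self.dvr_cutoff)
        self.reference_ = ref
        self.stats_ = {m: fit_reference_stats(ref, m) for m in mods}
        self.modalities_ = mods
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        panel = self._with_gba(X)
        rows = []
        gmm_inputs: dict[str, list] = {m: [] for m in self.modalities_}
        for m in self.modalities_:
            st = self.stats_[m]
            vals = panel[m].to_numpy(dtype=float)
            if st.kind == "simple":
                with np.errstate(invalid="ignore"):
                    z = (vals - st.mean) / st.sd
            else:
                ticv = panel["ticv"].to_numpy(dtype=float)
                with np.errstate(invalid="ignore"):
                    z = (vals - (st.intercept + st.slope_ticv * ticv)) / st.rmse
            direction = MODALITY_DIRECTIONS[m]
            for pid, v, zz in zip(panel["participant_id"], vals, z):
                rows.append(
                    {
                        "participant_id": pid,
                        "modality": m,
                        "value": v,
                        "z": zz,
                        "positive_primary": bool(threshold_positive(zz, direction, self.z_cutoff))
                        if np.isfinite(zz)
                        else np.nan,
                    }
                )
        out = pd.DataFrame(rows)
        if self.gmm:
            out["positive_secondary"] = np.nan
            self.gmm_cutoffs_ = {}
            seeds = np.random.SeedSequence(self.seed).spawn(len(self.modalities_))
            for m, s in zip(self.modalities_, seeds):
                sel = (out["modality"] == m) & np.isfinite(out["z"])
                zv = out.loc[sel, "z"].to_numpy()
                if zv.size < 20:
                    warnings.warn(f"{m}: too few values for GMM positivity; skipped")
                    continue
                cutoff, flags, info = gmm_positivity(
                    zv, MODALITY_DIRECTIONS[m], seed=s
                )
                out.loc[sel, "positive_secondary"] = flags
                self.gmm_cutoffs_[m] = {"cutoff": cutoff, **{
                    k: np.asarray(v).tolist() if isinstance(v, np.ndarray) else v
                    for k, v in info.items()
                }}
        if "dvr" in panel.columns:
            amy = panel[["participant_id", "dvr"]].copy()
            amy["amyloid_positive"] = np.where(
                amy["dvr"].notna(), amy["dvr"] > self.dvr_cutoff, np.nan
            )
            self.amyloid_calls_ = amy
        return out

    def stats_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.stats_.values()])
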