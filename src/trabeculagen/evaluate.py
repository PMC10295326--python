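"""Similarity metrics and the statistical battery.

Similarity between generated and reference images is scored with SSIM
(windowed structural similarity on registered slice pairs) and FID (the
Fréchet distance between Gaussian fits to feature embeddings of two image
sets).  The canonical FID embedding is a pretrained Inception network; this
package instead ships a seed-frozen random convolutional projector, so FID
values are comparable only within a run configuration — every report states
the extractor used.  A hook accepts any user-supplied embedding function.

The statistics cover the comparisons a method-validation study needs:
Friedman (>= 3 related groups), Mann-Whitney U (2 independent groups),
paired t, Kolmogorov-Smirnov normality and Levene homogeneity pre-checks,
ordinary least squares with R^2 and F, Fisher-z comparison of two
correlations, and ICC(2,1) (two-way random effects, absolute agreement,
single measures) with its F-based 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.metrics import structural_similarity

from .core import VoxelVolume

__all__ = [
    "SimilarityReport",
    "StatsReport",
    "ssim",
    "RandomConvProjector",
    "embed",
    "fid",
    "cancellous_crop",
    "compare_methods",
    "regress_metrics",
    "compare_correlations",
    "icc",
    "full_report",
]


@dataclass
class SimilarityReport:
    scope: str  # "overall" | "cancellous"
    ssim_values: np.ndarray
    fid_value: float
    pairing: str = "ground-truth"
    extractor: str = "random-conv-projector"

    @property
    def ssim_mean(self) -> float:
        return float(np.mean(self.ssim_values))

    @property
    def ssim_sd(self) -> float:
        return float(np.std(self.ssim_values))


@dataclass
class StatsReport:
    test: str
    statistic: float
    p_value: float
    effect: dict = field(default_factory=dict)
    groups: tuple = ()


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------

def ssim(a, b, data_range: float = 255.0) -> float:
    """Structural similarity with the standard 11x11 Gaussian window
    (sigma 1.5) and constants C1=(0.01 L)^2, C2=(0.03 L)^2."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(
        structural_similarity(
            a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, win_size=11,
        )
    )


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------

class RandomConvProjector:
    """Seed-frozen random convolutional feature extractor.

    Three stride-2 valid convolutions with fixed Gaussian weights and ReLU,
    then channel-wise global mean and standard deviation pooling.  Weights
    depend only on the seed, so embeddings are reproducible.
    """

    def __init__(self, seed: int = 0, channels=(8, 16, 32), k: int = 5):
        rng = np.random.default_rng(seed)
        self.filters = []
        cin = 1
        for c in channels:
            w = rng.standard_normal((c, cin, k, k)).astype(np.float32)
            w /= np.sqrt(cin * k * k)
            self.filters.append(w)
            cin = c
        self.name = f"random-conv-projector(seed={seed})"

    def __call__(self, images) -> np.ndarray:
        a = np.asarray(images, dtype=np.float32)
        if a.ndim == 2:
            a = a[None]
        x = (a[:, None] / 127.5) - 1.0  # (n, 1, h, w)
        from numpy.lib.stride_tricks import sliding_window_view

        for w in self.filters:
            co, ci, kh, kw = w.shape
            v = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::2, ::2]
            x = np.einsum("nchwij,ocij->nohw", v, w, optimize=True)
            x = np.maximum(x, 0.0)
        mu = x.mean(axis=(2, 3))
        sd = x.std(axis=(2, 3))
        return np.concatenate([mu, sd], axis=1)


def embed(images, extractor=None) -> np.ndarray:
    """One fixed-length feature vector per image."""
    if extractor is None:
        extractor = RandomConvProjector()
    return np.asarray(extractor(images), dtype=np.float64)


def fid(features_a, features_b, ridge: float = 1e-9) -> float:
    """Fréchet distance between Gaussian fits of two feature sets:
    ||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^(1/2)).

    The matrix square root is taken symmetrically via eigendecomposition of
    sqrt(S1) S2 sqrt(S1); tiny negative eigenvalues (below -1e-8) raise, the
    rest are clipped to zero.  Near-singular covariances are regularized
    with a logged ridge.
    """
    a = np.atleast_2d(np.asarray(features_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(features_b, dtype=np.float64))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions differ")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 vectors per set for a covariance")
    mu1, mu2 = a.mean(axis=0), b.mean(axis=0)
    s1 = np.atleast_2d(np.cov(a, rowvar=False))
    s2 = np.atleast_2d(np.cov(b, rowvar=False))
    s1 = s1 + ridge * np.eye(s1.shape[0])
    s2 = s2 + ridge * np.eye(s2.shape[0])
    # symmetric square root of s1
    w, v = np.linalg.eigh(s1)
    w = np.clip(w, 0.0, None)
    rs1 = (v * np.sqrt(w)) @ v.T
    m = rs1 @ s2 @ rs1
    ev = np.linalg.eigvalsh((m + m.T) / 2.0)
    if ev.min() < -1e-8:
        raise np.linalg.LinAlgError(f"covariance product has eigenvalue {ev.min()}")
    tr_sqrt = np.sqrt(np.clip(ev, 0.0, None)).sum()
    d2 = float(np.sum((mu1 - mu2) ** 2) + np.trace(s1) + np.trace(s2) - 2.0 * tr_sqrt)
    return max(d2, 0.0)


# ---------------------------------------------------------------------------
# cancellous scope
# ---------------------------------------------------------------------------

def cancellous_crop(volume, body_mask, cortical_thickness_mm: float = 0.4,
                    margin_mm: float = 0.0):
    """Crop an image (stack) to the cancellous interior of the body mask.

    The body mask is eroded by the cortical thickness plus a margin (an
    exact Euclidean-distance erosion), and the bounding box of the eroded
    region is cut out of the volume.  Returns ``(cropped, eroded_mask)``.
    """
    vol = volume if isinstance(volume, VoxelVolume) else None
    data = volume.data if vol is not None else np.asarray(volume)
    mask = body_mask.data.astype(bool) if isinstance(body_mask, VoxelVolume) else np.asarray(body_mask, bool)
    if data.shape != mask.shape:
        raise ValueError("volume and body mask shapes differ")
    sampling = vol.voxel_size if vol is not None else (1.0, 1.0, 1.0)
    if mask.ndim == 2:
        sampling = sampling[-2:] if vol is not None else (1.0, 1.0)
    dist = ndimage.distance_transform_edt(mask, sampling=sampling)
    depth = cortical_thickness_mm + margin_mm
    eroded = dist > depth
    if not eroded.any():
        raise ValueError("mask is empty after erosion; reduce the margin")
    idx = np.nonzero(eroded)
    sl = tuple(slice(i.min(), i.max() + 1) for i in idx)
    cropped = data[sl]
    if vol is not None:
        cropped = vol.with_data(cropped)
    return cropped, eroded[sl]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

ALPHA = 0.05


def compare_methods(reference: dict | np.ndarray, methods: dict) -> list[StatsReport]:
    """Standard comparison battery over per-item metric values.

    ``methods`` maps method name -> 1-D array of paired observations (same
    items in the same order).  Runs K-S normality and Levene homogeneity
    pre-checks, a Friedman test across all groups (>= 3 groups), and paired
    tests of each method against the reference (two-sided, alpha 0.05):
    Mann-Whitney U (independent-samples view) and paired t.
    """
    ref = np.asarray(reference, dtype=float)
    if not methods:
        raise ValueError("no methods to compare")
    groups = {name: np.asarray(v, dtype=float) for name, v in methods.items()}
    for name, v in groups.items():
        if v.shape != ref.shape:
            raise ValueError(f"method {name!r} is not paired with the reference")
    out = []
    for name, v in groups.items():
        z = (v - v.mean()) / v.std() if v.std() > 0 else v - v.mean()
        ks = stats.kstest(z, "norm")
        out.append(StatsReport("kolmogorov-smirnov", float(ks.statistic), float(ks.pvalue),
                               groups=(name,)))
    lev = stats.levene(ref, *groups.values())
    out.append(StatsReport("levene", float(lev.statistic), float(lev.pvalue),
                           groups=("reference", *groups)))
    if len(groups) >= 2:
        if all(np.array_equal(v, ref) for v in groups.values()):
            # all rankings tied: no evidence of any difference
            out.append(StatsReport("friedman", 0.0, 1.0, groups=("reference", *groups)))
        else:
            fr = stats.friedmanchisquare(ref, *groups.values())
            out.append(StatsReport("friedman", float(fr.statistic), float(fr.pvalue),
                                   groups=("reference", *groups)))
    for name, v in groups.items():
        if np.allclose(v, ref):
            out.append(StatsReport("mann-whitney-u", float(len(v) * len(ref) / 2.0), 1.0,
                                   groups=(name, "reference")))
            out.append(StatsReport("paired-t", 0.0, 1.0, groups=(name, "reference")))
            continue
        u = stats.mannwhitneyu(v, ref, alternative="two-sided")
        out.append(StatsReport("mann-whitney-u", float(u.statistic), float(u.pvalue),
                               groups=(name, "reference")))
        t = stats.ttest_rel(v, ref)
        out.append(StatsReport("paired-t", float(t.statistic), float(t.pvalue),
                               groups=(name, "reference")))
    return out


def regress_metrics(x, y) -> StatsReport:
    """OLS of generated (y) on reference (x): slope, intercept, R^2 and the
    overall F statistic F = R^2 (n-2) / (1 - R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    n = x.size
    f = r2 * (n - 2) / (1 - r2) if r2 < 1 else np.inf
    return StatsReport(
        "ols", float(f), float(res.pvalue),
        effect={"slope": float(res.slope), "intercept": float(res.intercept),
                "r2": float(r2), "f": float(f), "n": int(n)},
    )


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher z-test for the difference of two independent correlations:
    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 per sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def icc(pairs) -> StatsReport:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measures, with the F-distribution 95% confidence interval."""
    a = np.asarray(pairs, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of paired measurements")
    if a.shape[0] < 5:
        raise ValueError("need at least 5 pairs")
    if np.ptp(a) == 0:
        raise ValueError("zero total variance")
    import pingouin as pg

    n = a.shape[0]
    df = pd.DataFrame({
        "targets": np.repeat(np.arange(n), 2),
        "raters": np.tile([0, 1], n),
        "score": a.ravel(),
    })
    tab = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="score")
    row = tab[tab["Type"] == "ICC(A,1)"].iloc[0]  # absolute agreement, single
    ci_col = "CI95%" if "CI95%" in tab.columns else "CI95"
    return StatsReport(
        "icc(2,1)", float(row["ICC"]), float(row["pval"]),
        effect={"ci95": tuple(float(v) for v in row[ci_col]), "n": int(n)},
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def full_report(similarity: dict, statistics: list, out_dir) -> dict:
    """Assemble similarity and statistics into metrics.csv, stats.csv and a
    readable summary.txt under ``out_dir``; returns the written paths."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not similarity:
        raise ValueError("no similarity reports to write")
    rows = []
    for method, reps in similarity.items():
        for rep in (reps if isinstance(reps, (list, tuple)) else [reps]):
            rows.append({
                "method": method, "scope": rep.scope,
                "ssim_mean": rep.ssim_mean, "ssim_sd": rep.ssim_sd,
                "fid": rep.fid_value, "n_pairs": len(rep.ssim_values),
                "extractor": rep.extractor, "pairing": rep.pairing,
            })
    metrics = pd.DataFrame(rows)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    srows = [{
        "test": s.test, "statistic": s.statistic, "p_value": s.p_value,
        "groups": "|".join(map(str, s.groups)), **{f"effect_{k}": v for k, v in s.effect.items()},
    } for s in statistics]
    stats_path = out / "stats.csv"
    pd.DataFrame(srows).to_csv(stats_path, index=False)
    summary = out / "summary.txt"
    with open(summary, "w") as fh:
        fh.write("Similarity metrics (FID extractor: seed-frozen random "
                 "convolutional projector; values comparable only within "
                 "one run configuration)\n")
        fh.write(metrics.to_string(index=False))
        fh.write("\n\nStatistics (two-sided, alpha = 0.05)\n")
        for s in statistics:
            fh.write(f"  {s.test:22s} stat={s.statistic:10.4f} p={s.p_value:.4g} "
                     f"{s.effect if s.effect else ''}\n")
    return {"metrics": metrics_path, "stats": stats_path, "summary": summary}
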