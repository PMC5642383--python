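"""Synthetic cohorts with known causal structure.

Real inputs for this kind of analysis are controlled-access somatic mutation
cohorts and large public epigenome panels; the generator replaces them with
window-level data whose generating model is fully known, so that recovery
can be asserted:

* **Features** — per tissue/cell-type category, assay tracks are drawn from a
  lag-1 autocorrelated Gaussian process over window index (chromatin signal
  is smooth at the megabase scale), with a configurable within-category
  cross-correlation ``rho`` (marks from the same tissue co-vary), then
  affinely mapped to a nonnegative signal-like range.
* **Mutations** — the per-window log mutation rate is linear in a small set
  of standardized causal features: λ_i = exp(baseline + Σ_k β_k z_ik);
  per-sample counts are Poisson(λ_i · scale) (negative binomial when an
  overdispersion parameter is set), with positions uniform in the window and
  random distinct ref/alt nucleotides.
* **Paired cohorts** — a cancer sample re-uses a configurable fraction of its
  matched precancer sample's mutations plus fresh draws from its own rate
  model, emulating matched precancer/cancer genome pairs.
* **Metaplasia scenario** — two correlated tissue tracks where a planted set
  of windows gets an additive boost in the "target" tissue while mutation
  rates follow the "source" tissue, the construction used to test
  differential-region selection and prediction.

Everything is deterministic under a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seeds
from .catalog import MutationCatalog, RECORD_COLUMNS, concat_catalogs
from .features import FeatureMatrix, FeatureTrack
from .windows import WindowSet, make_windows

NUCLEOTIDES = np.array(list("ACGT"))

DEFAULT_MARKS = ["H3K27me3", "H3K36me3", "H3K4me1", "H3K4me3", "H3K9me3"]

# defaults chosen so that, at 20 samples, the summed group density is
# strongly but not perfectly explained by the causal set (full-model OOB
# variance explained around 0.7-0.85)
DEFAULT_BETAS = (0.4, 0.5, 0.6, 0.7, 0.8)
DEFAULT_BASELINE_LOG_RATE = 0.0  # ~1 mutation / Mb / sample at the feature mean
DEFAULT_RHO = 0.5
DEFAULT_LAG1 = 0.5

SIGNAL_LOC = 100.0
SIGNAL_SCALE = 20.0


@dataclass
class SyntheticTruth:
    causal_features: list[str]
    betas: np.ndarray
    baseline_log_rate: float = DEFAULT_BASELINE_LOG_RATE
    dispersion: float | None = None  # None = Poisson; else NB shape parameter
    feature_correlation: float = DEFAULT_RHO
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.betas) != len(self.causal_features):
            raise ValueError("betas and causal_features must have equal length")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive when set")

    def to_json_dict(self) -> dict:
        return {
            "causal_features": list(self.causal_features),
            "betas": self.betas.tolist(),
            "baseline_log_rate": self.baseline_log_rate,
            "dispersion": self.dispersion,
            "feature_correlation": self.feature_correlation,
            "seed": self.seed,
            "extras": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.extras.items()
            },
        }


@dataclass
class SyntheticCohort:
    window_set: WindowSet
    feature_matrix: FeatureMatrix
    catalog: MutationCatalog
    truth: SyntheticTruth


def _ar1(rng: np.random.Generator, n: int, lag1: float) -> np.ndarray:
    """Stationary AR(1) series with unit marginal variance."""
    eps = rng.standard_normal(n)
    z = np.empty(n)
    z[0] = eps[0]
    c = np.sqrt(1.0 - lag1 ** 2)
    for t in range(1, n):
        z[t] = lag1 * z[t - 1] + c * eps[t]
    return z


def gen_features(
    ws: WindowSet | int,
    categories: list[tuple[str, list[str]]] | None = None,
    rho: float = DEFAULT_RHO,
    lag1: float = DEFAULT_LAG1,
    seed: int = 0,
) -> FeatureMatrix:
    """Draw a per-window feature panel.

    ``categories`` is a list of (category name, assay names); the default is
    six tissue-like categories carrying the five common histone marks each.
    Within a category, tracks share a latent component so their pairwise
    correlation is ``rho``.
    """
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    W = len(ws) if isinstance(ws, WindowSet) else int(ws)
    if W < 50:
        raise ValueError("need at least 50 windows for a usable panel")
    if categories is None:
        categories = [(f"tissue{i}", list(DEFAULT_MARKS)) for i in range(6)]
    tracks = []
    for ci, (cname, assays) in enumerate(categories):
        common = _ar1(_seeds.rng(seed, _seeds.SIMULATE, 0, ci), W, lag1)
        for ai, assay in enumerate(assays):
            own = _ar1(_seeds.rng(seed, _seeds.SIMULATE, 1, ci, ai), W, lag1)
            z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * own
            values = np.clip(SIGNAL_LOC + SIGNAL_SCALE * z, 0.0, None)
            tracks.append(
                FeatureTrack(f"{cname}_{assay}", values, category=cname,
                             assay=assay)
            )
    window_ref = ws if isinstance(ws, WindowSet) else None
    return FeatureMatrix(tracks, window_ref=window_ref)


def expected_rates(features: FeatureMatrix, truth: SyntheticTruth) -> np.ndarray:
    """λ_i = exp(baseline + Σ β_k z_ik) with z the standardized causal columns."""
    lograte = np.full(features.n_windows, truth.baseline_log_rate)
    for name, beta in zip(truth.causal_features, truth.betas):
        v = features.track(name).values
        sd = v.std()
        if sd == 0:
            raise ValueError(f"causal feature {name!r} is constant")
        lograte = lograte + beta * (v - v.mean()) / sd
    return np.exp(lograte)


def _records_for_counts(
    rng: np.random.Generator, ws: WindowSet, counts: np.ndarray, sample_id: str
) -> pd.DataFrame:
    total = int(counts.sum())
    chroms = np.empty(total, dtype=object)
    pos = np.empty(total, dtype=np.int64)
    at = 0
    for win, k in zip(ws, counts):
        k = int(k)
        if k == 0:
            continue
        chroms[at:at + k] = win.chrom
        pos[at:at + k] = rng.integers(win.start, win.end, size=k)
        at += k
    ref_idx = rng.integers(0, 4, size=total)
    alt_off = rng.integers(1, 4, size=total)
    rec = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": NUCLEOTIDES[ref_idx],
            "alt": NUCLEOTIDES[(ref_idx + alt_off) % 4],
            "sample_id": sample_id,
        }
    )
    return rec[RECORD_COLUMNS]


def gen_mutations(
    features: FeatureMatrix,
    truth: SyntheticTruth,
    n_samples: int,
    per_sample_rate_scale: float = 1.0,
    seed: int = 0,
    ws: WindowSet | None = None,
    cohort: str = "synthetic",
    sample_prefix: str = "S",
    ighv_status: str = "NA",
    dysplasia: str | list[str] = "NA",
) -> MutationCatalog:
    """Draw per-sample mutation catalogs from the log-linear rate model."""
    if per_sample_rate_scale <= 0:
        raise ValueError("per_sample_rate_scale must be positive")
    ws = ws or features.window_ref
    if ws is None:
        raise ValueError("a WindowSet is required (features.window_ref unset)")
    lam = expected_rates(features, truth) * per_sample_rate_scale
    grades = ([dysplasia] * n_samples if isinstance(dysplasia, str)
              else list(dysplasia))
    if len(grades) != n_samples:
        raise ValueError("dysplasia list length must equal n_samples")
    recs = []
    meta_rows = []
    for s in range(n_samples):
        rng = _seeds.rng(seed, _seeds.SIMULATE, 2, s)
        if truth.dispersion is None:
            counts = rng.poisson(lam)
        else:
            d = truth.dispersion
            counts = rng.poisson(rng.gamma(d, lam / d))
        sid = f"{sample_prefix}{s:03d}"
        recs.append(_records_for_counts(rng, ws, counts, sid))
        meta_rows.append(
            {"sample_id": sid, "cohort": cohort, "ighv_status": ighv_status,
             "dysplasia": grades[s], "pair_id": "NA"}
        )
    records = pd.concat(recs, ignore_index=True) if recs else pd.DataFrame(
        columns=RECORD_COLUMNS)
    return MutationCatalog(records, pd.DataFrame(meta_rows))


def gen_paired_cohort(
    features: FeatureMatrix,
    truth_pre: SyntheticTruth,
    truth_cancer: SyntheticTruth | None,
    shared_fraction: float,
    n_pairs: int,
    seed: int = 0,
    per_sample_rate_scale: float = 1.0,
    ws: WindowSet | None = None,
    precancer_cohort: str = "precancer",
    cancer_cohort: str = "cancer",
    dysplasia_grades: list[str] | None = None,
) -> SyntheticCohort:
    """Matched precancer/cancer pairs sharing a fraction of mutations.

    Each pair draws a precancer catalog from ``truth_pre``; the cancer member
    keeps each precancer mutation independently with probability
    ``shared_fraction`` and adds fresh draws from ``truth_cancer`` (none when
    ``truth_cancer`` is None).  The realized shared fraction is recorded in
    ``truth.extras['realized_shared_fraction']``.
    """
    if not (0 <= shared_fraction <= 1):
        raise ValueError("shared_fraction must be in [0, 1]")
    ws = ws or features.window_ref
    if ws is None:
        raise ValueError("a WindowSet is required")
    grades = dysplasia_grades or ["NA"] * n_pairs
    if len(grades) != n_pairs:
        raise ValueError("dysplasia_grades length must equal n_pairs")
    catalogs = []
    n_pre_total = 0
    n_shared_total = 0
    for p in range(n_pairs):
        pre = gen_mutations(
            features, truth_pre, 1, per_sample_rate_scale,
            seed=_seeds.derive_int(seed, 20, p), ws=ws, cohort=precancer_cohort,
            sample_prefix=f"pre{p:02d}_", dysplasia=grades[p],
        )
        rng = _seeds.rng(seed, 21, p)
        keep = rng.random(len(pre.records)) < shared_fraction
        shared_rec = pre.records.loc[keep].copy()
        n_pre_total += len(pre.records)
        n_shared_total += int(keep.sum())
        can_sid = f"can{p:02d}_000"
        shared_rec["sample_id"] = can_sid
        parts = [shared_rec]
        if truth_cancer is not None:
            fresh = gen_mutations(
                features, truth_cancer, 1, per_sample_rate_scale,
                seed=_seeds.derive_int(seed, 22, p), ws=ws,
                cohort=cancer_cohort, sample_prefix=f"can{p:02d}_",
            )
            parts.append(fresh.records)
        can_rec = pd.concat(parts, ignore_index=True)
        pair_id = f"pair{p:02d}"
        meta = pd.DataFrame(
            [
                {"sample_id": pre.sample_ids[0], "cohort": precancer_cohort,
                 "ighv_status": "NA", "dysplasia": grades[p], "pair_id": pair_id},
                {"sample_id": can_sid, "cohort": cancer_cohort,
                 "ighv_status": "NA", "dysplasia": "NA", "pair_id": pair_id},
            ]
        )
        catalogs.append(MutationCatalog(
            pd.concat([pre.records, can_rec], ignore_index=True), meta))
    catalog = concat_catalogs(catalogs)
    truth = SyntheticTruth(
        truth_pre.causal_features, truth_pre.betas,
        truth_pre.baseline_log_rate, truth_pre.dispersion,
        truth_pre.feature_correlation, seed,
        extras={
            "shared_fraction": shared_fraction,
            "realized_shared_fraction": (
                n_shared_total / n_pre_total if n_pre_total else float("nan")
            ),
        },
    )
    return SyntheticCohort(ws, features, catalog, truth)


def gen_metaplasia_scenario(
    W: int = 400,
    n_planted: int = 15,
    boost_sd: float = 3.0,
    seed: int = 0,
    source_target_corr: float = 0.7,
    beta: float = 0.6,
    n_samples: int = 20,
    per_sample_rate_scale: float = 1.0,
    window_size: int = 1_000_000,
    lag1: float = DEFAULT_LAG1,
    boost_jitter: float = 0.0,
    rate_noise_sd: float = 1.0,
) -> SyntheticCohort:
    """Cell-type-shift construction for differential-region analysis.

    Two correlated tracks of the same mark — "source" (the tissue state the
    cells shifted toward, which drives mutation rates) and "target" (the
    tissue of origin) — plus ``n_planted`` windows where the target track
    gets an additive boost of ``boost_sd ± boost_jitter`` signal-σ.  The log
    mutation rate is β·z_source plus a per-window lognormal distortion whose
    standard deviation shrinks linearly with the realized target − source
    difference (``rate_noise_sd`` at zero difference, 0 at ``boost_sd``·σ):
    the chromatin difference measures how established the cell-state shift
    is, so large-difference windows follow the source-state rate faithfully
    while small-difference windows deviate.  The planting record (indices
    and boosts) is stored in ``truth.extras``.
    """
    if W < 200:
        raise ValueError("need at least 200 windows for this scenario")
    ws = make_windows({"chr1": W * window_size}, window_size,
                      genome_label="synthetic")
    rng = _seeds.rng(seed, 30)
    src_z = _ar1(_seeds.rng(seed, 30, 0), W, lag1)
    own_z = _ar1(_seeds.rng(seed, 30, 1), W, lag1)
    tgt_z = source_target_corr * src_z + np.sqrt(
        1.0 - source_target_corr ** 2) * own_z
    source = np.clip(SIGNAL_LOC + SIGNAL_SCALE * src_z, 0.0, None)
    target0 = np.clip(SIGNAL_LOC + SIGNAL_SCALE * tgt_z, 0.0, None)
    planted = np.sort(rng.choice(W, size=n_planted, replace=False))
    boosts = boost_sd + boost_jitter * rng.uniform(-1.0, 1.0, size=n_planted)
    target = target0.copy()
    target[planted] += boosts * SIGNAL_SCALE
    z_src = (source - source.mean()) / source.std()
    # shift completeness from the realized chromatin difference
    diff_sd_units = (target - source) / SIGNAL_SCALE
    completeness = (np.clip(diff_sd_units / (1.5 * boost_sd), 0.0, 1.0)
                    if boost_sd > 0 else np.zeros(W))
    dist_sd = rate_noise_sd * (1.0 - completeness)
    # mean-corrected lognormal distortion: E[exp(distortion)] = 1 per window
    distortion = (dist_sd * _seeds.rng(seed, 30, 2).standard_normal(W)
                  - 0.5 * dist_sd ** 2)
    fm = FeatureMatrix(
        [
            FeatureTrack("source_H3K4me1", source, category="source_tissue",
                         assay="H3K4me1"),
            FeatureTrack("target_H3K4me1", target, category="target_tissue",
                         assay="H3K4me1"),
            FeatureTrack("_rate_driver", beta * z_src + distortion,
                         category="latent", assay="latent"),
        ],
        window_ref=ws,
    )
    # expected_rates standardizes causal columns; a beta equal to the driver's
    # SD makes the realized log-rate exactly baseline + (driver − mean)
    driver_sd = float(fm.track("_rate_driver").values.std())
    truth = SyntheticTruth(
        ["_rate_driver"], [driver_sd], seed=seed,
        extras={"planted_indices": planted, "boosts_sd_units": boosts,
                "boost_sd": boost_sd, "boost_jitter": boost_jitter,
                "rate_noise_sd": rate_noise_sd, "beta": beta,
                "source_target_corr": source_target_corr},
    )
    catalog = gen_mutations(
        fm, truth, n_samples, per_sample_rate_scale,
        seed=_seeds.derive_int(seed, 31), ws=ws, cohort="precancer_nd",
        dysplasia="ND",
    )
    # the latent driver is generator bookkeeping, not an observable feature
    observed = FeatureMatrix(fm.tracks[:2], window_ref=ws)
    return SyntheticCohort(ws, observed, catalog, truth)


def default_truth(
    features: FeatureMatrix,
    causal_category: str = "tissue0",
    betas=DEFAULT_BETAS,
    seed: int = 0,
    **kwargs,
) -> SyntheticTruth:
    """Truth whose causal set is one tissue category's tracks (field defaults)."""
    members = [t.name for t in features.tracks if t.category == causal_category]
    if not members:
        raise ValueError(f"no tracks in category {causal_category!r}")
    betas = np.asarray(betas, dtype=float)
    if len(betas) < len(members):
        raise ValueError("not enough betas for the causal category")
    return SyntheticTruth(members, betas[: len(members)], seed=seed, **kwargs)


def default_cohort(
    W: int = 400,
    n_categories: int = 6,
    seed: int = 0,
    n_samples: int = 20,
    rho: float = DEFAULT_RHO,
    window_size: int = 1_000_000,
    betas=DEFAULT_BETAS,
    dispersion: float | None = None,
) -> SyntheticCohort:
    """The standard test cohort: W windows, n_categories × 5 marks, one
    causal tissue category with effects ``betas``, summed over ``n_samples``
    Poisson samples."""
    ws = make_windows({"chr1": W * window_size}, window_size,
                      genome_label="synthetic")
    cats = [(f"tissue{i}", list(DEFAULT_MARKS)) for i in range(n_categories)]
    fm = gen_features(ws, cats, rho=rho, seed=seed)
    truth = default_truth(fm, "tissue0", betas, seed=seed,
                          feature_correlation=rho, dispersion=dispersion)
    catalog = gen_mutations(fm, truth, n_samples,
                            seed=_seeds.derive_int(seed, 40), ws=ws)
    return SyntheticCohort(ws, fm, catalog, truth)


def paper_scale_panel(W: int, seed: int = 0) -> FeatureMatrix:
    """A 423-track load-testing panel: 9 tissue categories × 47 assays."""
    assays = DEFAULT_MARKS + [f"assay{i}" for i in range(42)]
    cats = [(f"tissue{i}", list(assays)) for i in range(9)]
    ws = make_windows({"chr1": W * 1_000_000}, 1_000_000)
    return gen_features(ws, cats, seed=seed)
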