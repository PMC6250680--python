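"""Isobaric-label (iTRAQ-style) phosphoproteome quantification.

The quantification chain mirrors standard reporter-ion practice: peptides are
filtered on label presence, spectrum sharing, intensity and identification
confidence; channels are bias-corrected under the equal-total-signal
assumption; fragment intensities covering a phosphorylation site are combined
by geometric mean; per-site case/control ratios are weighted geometric means
of peptide ratios; and differential phosphorylation is called by Welch's test
on log ratios with Benjamini-Hochberg adjustment across sites.

Ratios are modelled as log-normal throughout, so every aggregation happens on
the log scale and is back-transformed: natural log internally, log2 for
reported fold changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, welch_test

logger = logging.getLogger(__name__)

__all__ = [
    "META_COLUMNS",
    "ReporterMatrix",
    "filter_peptides",
    "normalize_channels",
    "fragment_site_quantity",
    "peptide_ratio",
    "protein_site_ratio",
    "site_differential_test",
]

#: Metadata columns every reporter table carries ahead of the channel columns.
META_COLUMNS = [
    "peptide",
    "fragment",
    "protein",
    "site",
    "confidence",
    "has_itraq_label",
    "shared_spectrum",
]


@dataclass
class ReporterMatrix:
    """Fragment-level reporter-ion intensities with peptide metadata.

    ``data`` holds one row per MS/MS fragment (identified by ``peptide`` and
    ``fragment``) with the metadata columns of :data:`META_COLUMNS` followed by
    one intensity column per channel. ``groups`` maps each channel name to
    ``"case"`` or ``"control"``.
    """

    data: pd.DataFrame
    channels: list[str]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"reporter table lacks metadata columns: {missing}")
        missing = [c for c in self.channels if c not in self.data.columns]
        if missing:
            raise ValueError(f"reporter table lacks channel columns: {missing}")
        bad = set(self.groups.values()) - {"case", "control"}
        if bad:
            raise ValueError(f"channel groups must be 'case' or 'control', got {bad}")
        inten = self.data[self.channels].to_numpy(dtype=float)
        if np.any(inten < 0) or np.any(~np.isfinite(inten)):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def case_channels(self) -> list[str]:
        return [c for c in self.channels if self.groups.get(c) == "case"]

    @property
    def control_channels(self) -> list[str]:
        return [c for c in self.channels if self.groups.get(c) == "control"]

    @property
    def intensities(self) -> pd.DataFrame:
        return self.data[self.channels]

    def copy_with(self, data: pd.DataFrame) -> "ReporterMatrix":
        return ReporterMatrix(data=data, channels=list(self.channels), groups=dict(self.groups))


def filter_peptides(
    m: ReporterMatrix,
    min_intensity: float | None = None,
    min_confidence: float = 0.95,
) -> ReporterMatrix:
    """Remove peptides that cannot be quantified reliably.

    Drops rows without an iTRAQ label, rows flagged as sharing MS/MS spectra
    with other proteins, rows whose maximum channel intensity falls below
    ``min_intensity`` (default: the 1% quantile of all intensities), and rows
    whose identification confidence is not strictly above ``min_confidence``.
    """
    df = m.data
    inten = df[m.channels].to_numpy(dtype=float)
    if min_intensity is None:
        min_intensity = float(np.quantile(inten, 0.01)) if inten.size else 0.0
    keep = (
        df["has_itraq_label"].astype(bool)
        & ~df["shared_spectrum"].astype(bool)
        & (inten.max(axis=1) >= min_intensity)
        & (df["confidence"].astype(float) > min_confidence)
    )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "filter_peptides: removed %d/%d fragment rows (no label: %d, shared: %d, "
            "low intensity: %d, low confidence: %d)",
            n_drop,
            len(df),
            int((~df["has_itraq_label"].astype(bool)).sum()),
            int(df["shared_spectrum"].astype(bool).sum()),
            int((inten.max(axis=1) < min_intensity).sum()),
            int((df["confidence"].astype(float) <= min_confidence).sum()),
        )
    return m.copy_with(df.loc[keep].reset_index(drop=True))


def normalize_channels(m: ReporterMatrix) -> ReporterMatrix:
    """Bias-correct channels so every channel's total signal is equal.

    Each channel is rescaled to the grand mean of the original channel totals,
    preserving relative intensities within a channel. Idempotent.
    """
    df = m.data.copy()
    totals = df[m.channels].sum(axis=0).to_numpy(dtype=float)
    if np.any(totals <= 0):
        bad = [c for c, t in zip(m.channels, totals) if t <= 0]
        raise ValueError(f"channels with non-positive total signal: {bad}")
    target = totals.mean()
    df[m.channels] = df[m.channels].to_numpy(dtype=float) * (target / totals)
    return m.copy_with(df)


def fragment_site_quantity(fragment_intensities) -> float:
    """Geometric mean of the fragment intensities covering one site."""
    x = np.asarray(fragment_intensities, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one fragment intensity")
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError("fragment intensities must be positive and finite")
    return float(np.exp(np.mean(np.log(x))))


def peptide_ratio(case_intensities, control_intensities) -> float:
    """Case/control ratio for one peptide.

    Geometric mean of per-case-channel ratios against the geometric mean of
    the control channels — equivalently the back-transform of the mean log
    ratio.
    """
    case = np.asarray(case_intensities, dtype=float)
    ctrl = np.asarray(control_intensities, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("need at least one case and one control intensity")
    if np.any(case <= 0) or np.any(ctrl <= 0):
        raise ValueError("intensities must be positive")
    return float(np.exp(np.mean(np.log(case)) - np.mean(np.log(ctrl))))


def protein_site_ratio(peptide_ratios, weights=None) -> float:
    """Weighted geometric mean of peptide ratios for one protein or site.

    ``exp(sum(w_i * ln(r_i)) / sum(w_i))``; uniform weights when ``weights``
    is None. This same operation integrates multiple peptides covering one
    phosphorylation site.
    """
    r = np.asarray(peptide_ratios, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one peptide ratio")
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    if weights is None:
        w = np.ones_like(r)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != r.shape:
            raise ValueError("weights must match ratios in length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("weights must not all be zero")
    return float(np.exp(np.sum(w * np.log(r)) / w.sum()))


def _peptide_channel_quantities(m: ReporterMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate fragments to per-(protein, site, peptide) log channel quantities.

    Returns the log-scale quantities plus a per-peptide inverse-variance
    weight estimated from the fragment scatter around the per-channel mean
    ("error-factor" style weighting). Peptides with a single fragment get no
    variance estimate and fall back to weight 1.
    """
    df = m.data
    log_inten = np.log(df[m.channels].to_numpy(dtype=float))
    logged = pd.DataFrame(log_inten, columns=m.channels)
    logged[["protein", "site", "peptide"]] = df[["protein", "site", "peptide"]].values
    grouped = logged.groupby(["protein", "site", "peptide"], sort=True)
    mean_log = grouped[m.channels].mean()

    # residual variance of ln intensity within (peptide, channel) fragment sets
    var = grouped[m.channels].var(ddof=1)
    counts = grouped[m.channels].count()
    # variance of the per-channel mean: s^2 / n_frag, pooled over channels
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_var = (var / counts).mean(axis=1)
    weights = pd.Series(1.0, index=mean_log.index)
    ok = mean_var.notna() & (mean_var > 0)
    weights[ok] = 1.0 / mean_var[ok]
    return mean_log, weights


def site_differential_test(
    m: ReporterMatrix,
    alpha: float = 0.05,
    min_intensity: float | None = None,
    min_confidence: float = 0.95,
    normalize: bool = True,
    weighting: str = "inverse_variance",
) -> pd.DataFrame:
    """Full site-level differential phosphorylation analysis.

    Filters and bias-corrects the reporter matrix, integrates fragment and
    peptide quantities onto phosphorylation sites (weighted geometric means),
    computes per-channel log2 ratios against the control-channel geometric
    mean, applies Welch's test per site (case vs control log ratios) and the
    Benjamini-Hochberg adjustment across all tested sites.

    Returns a DataFrame with one row per (protein, site): ``n_peptides``,
    ``ratio``, ``log2_ratio``, ``p``, ``q``, ``significant``.
    """
    if weighting not in ("inverse_variance", "uniform"):
        raise ValueError("weighting must be 'inverse_variance' or 'uniform'")
    if len(m.case_channels) < 2 or len(m.control_channels) < 2:
        raise ValueError("need at least 2 case and 2 control channels for Welch's test")
    m = filter_peptides(m, min_intensity=min_intensity, min_confidence=min_confidence)
    if len(m.data) == 0:
        return pd.DataFrame(
            columns=["protein", "site", "n_peptides", "ratio", "log2_ratio", "p", "q", "significant"]
        )
    if normalize:
        m = normalize_channels(m)

    pep_log, pep_w = _peptide_channel_quantities(m)
    if weighting == "uniform":
        pep_w = pd.Series(1.0, index=pep_w.index)

    # weighted geometric mean across peptides covering the same site
    wsum = pep_w.groupby(level=["protein", "site"]).sum()
    site_log = (
        pep_log.mul(pep_w, axis=0).groupby(level=["protein", "site"]).sum().div(wsum, axis=0)
    )
    n_peptides = pep_w.groupby(level=["protein", "site"]).size()

    case_cols = m.case_channels
    ctrl_cols = m.control_channels
    ref = site_log[ctrl_cols].mean(axis=1)
    log2r = site_log.sub(ref, axis=0) / math.log(2)

    rows = []
    for (protein, site), lr in log2r.iterrows():
        case_vals = lr[case_cols].to_numpy(dtype=float)
        ctrl_vals = lr[ctrl_cols].to_numpy(dtype=float)
        res = welch_test(case_vals, ctrl_vals)
        est = float(case_vals.mean() - ctrl_vals.mean())
        rows.append(
            {
                "protein": protein,
                "site": site,
                "n_peptides": int(n_peptides.loc[(protein, site)]),
                "ratio": 2.0**est,
                "log2_ratio": est,
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out.sort_values(["protein", "site"]).reset_index(drop=True)
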