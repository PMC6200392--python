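"""Event-level filtering and descriptive statistics.

Operates on per-event tables (`pandas.DataFrame`) with one row per sliding
event. The canonical columns are:

=========================  =====================================================
column                     meaning
=========================  =====================================================
event_id                   unique identifier
condition                  condition label
ml1_nm, ml2_nm             microtubule lengths (nm)
initial_overlap_nm         overlap at the first imaged frame, L0 (nm)
v_phase1_nm_s              mean phase-1 sliding velocity (nm/s)
final_overlap_nm           stalled overlap length, L_FO (nm; NaN if no stall)
let1_nm, let2_nm           end-tag lengths (nm)
rho_untagged               initial untagged-overlap GFP density (A.U./nm)
n_microtubules             filaments identified in the bundle
encountered_bundle         sliding pair ran into another bundle
proximal_plus_ends_at_start  plus-ends already close at t = 0
overlap_edge_distinguishable overlap and moving end-tag edge resolvable
mt_edges_distinguishable   both filament edges resolvable
=========================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit

FLAG_COLUMNS = (
    "n_microtubules",
    "encountered_bundle",
    "proximal_plus_ends_at_start",
    "overlap_edge_distinguishable",
    "mt_edges_distinguishable",
)

ANALYSES = ("general", "velocity_vs_overlap", "length_vs_final_overlap")

MAX_OVERLAP_NM = 5000.0  # velocity-overlap analyses exclude longer overlaps


def filter_events(records: pd.DataFrame, analysis: str = "general"):
    """Split an event table into (included, excluded) with reason codes.

    Exclusion rules, applied in order (the first hit is the recorded reason):

    1. ``multiple_mts`` -- not exactly two microtubules in the bundle;
    2. ``bundle_encounter`` -- the sliding pair met another bundle;
    3. ``proximal_plus_ends`` -- plus-ends already close at the start (the
       sliding phase is too short to analyse);
    4. for ``velocity_vs_overlap``: ``overlap_edge_indistinct`` and
       ``overlap_gt_5um`` (initial overlaps above 5 um are excluded);
    5. for ``length_vs_final_overlap``: ``mt_edges_indistinct``.

    The split is a partition (every record lands in exactly one output) and
    the operation is idempotent on its included output.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis kind {analysis!r}; use one of {ANALYSES}")
    missing = [c for c in FLAG_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records lack required flag columns: {missing}")

    reasons = pd.Series("", index=records.index, dtype=object)

    def mark(mask, code):
        sel = mask & (reasons == "")
        reasons[sel] = code

    mark(records["n_microtubules"] != 2, "multiple_mts")
    mark(records["encountered_bundle"].astype(bool), "bundle_encounter")
    mark(records["proximal_plus_ends_at_start"].astype(bool), "proximal_plus_ends")
    if analysis == "velocity_vs_overlap":
        mark(~records["overlap_edge_distinguishable"].astype(bool),
             "overlap_edge_indistinct")
        mark(records["initial_overlap_nm"] > MAX_OVERLAP_NM, "overlap_gt_5um")
    elif analysis == "length_vs_final_overlap":
        mark(~records["mt_edges_distinguishable"].astype(bool),
             "mt_edges_indistinct")

    included = records[reasons == ""].copy()
    excluded = records[reasons != ""].copy()
    excluded["exclusion_reason"] = reasons[reasons != ""]
    return included, excluded


@dataclass(frozen=True)
class GaussianFit:
    mu: float
    sigma: float
    amplitude: float
    n: int
    residual: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def gaussian_fit(values, bin_width: float) -> GaussianFit:
    """Least-squares Gaussian on histogram counts with a fixed bin width.

    Mirrors fitting a histogram rather than a maximum-likelihood fit on the
    raw values; requires >= 20 values and non-degenerate spread.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError("need at least 20 values for a histogram fit")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: all values identical")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width + 0.5 * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(u, a, mu, sig):
        return a * np.exp(-0.5 * ((u - mu) / sig) ** 2)

    p0 = (counts.max(), float(x.mean()), max(float(x.std()), bin_width / 2))
    span = float(x.max() - x.min()) + bin_width
    bounds = ([0.0, x.min() - bin_width, bin_width / 10],
              [10.0 * counts.max(), x.max() + bin_width, 2.0 * span])
    popt, _ = curve_fit(gauss, centers, counts, p0=p0, bounds=bounds,
                        maxfev=10000)
    a, mu, sig = popt
    resid = float(np.sum((counts - gauss(centers, *popt)) ** 2))
    return GaussianFit(mu=float(mu), sigma=abs(float(sig)), amplitude=float(a),
                       n=int(x.size), residual=resid)


def pearson(x, y) -> float:
    """Sample Pearson correlation; NaN (flagged) for degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def linear_fit(x, y):
    """Ordinary least squares; returns (slope, intercept, r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def binned_means(x, y, bin_width: float) -> pd.DataFrame:
    """Per-bin mean, sd and count of y against binned x; empty bins omitted."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        return pd.DataFrame(columns=["bin_center", "mean", "sd", "n"])
    lo = np.floor(x.min() / bin_width) * bin_width
    idx = np.floor((x - lo) / bin_width).astype(int)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        rows.append(
            {
                "bin_center": lo + (b + 0.5) * bin_width,
                "mean": float(y[sel].mean()),
                "sd": float(y[sel].std(ddof=1)) if sel.sum() > 1 else 0.0,
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def molecules_per_micron(i_untagged: float, l_untagged_nm: float,
                         unit_intensity: float) -> float:
    """Molecule count density in the untagged overlap, per micrometre.

    ``unit_intensity`` is the calibrated fluorescence intensity of a single
    GFP-labelled molecule (A.U.), measured on immobilized single molecules.
    """
    if unit_intensity <= 0:
        raise ValueError("unit intensity must be positive")
    if l_untagged_nm <= 0:
        raise ValueError("untagged length must be positive")
    return i_untagged / (unit_intensity * l_untagged_nm) * 1000.0


def load_event_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read an event table from CSV or a spreadsheet, renaming columns.

    ``column_map`` maps canonical column names to the names used in the file,
    isolating assumptions about externally produced tables (e.g. published
    source-data spreadsheets) in one configuration object.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise ValueError(f"mapped columns missing from {path}: {missing}")
        df = df.rename(columns={src: dst for dst, src in column_map.items()})
    return df
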