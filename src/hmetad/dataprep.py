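"""Trial-level data ingestion and count-vector assembly.

Confidence-rating experiments usually produce a long table with one row
per trial (subject, stimulus, response, confidence).  The estimation
routines instead consume, per subject, the two stimulus-conditional count
vectors ``nR_S1`` and ``nR_S2`` of length 2k.  This module converts
between the two, bins continuous confidence ratings into quantiles, and
reads/writes the package's CSV formats.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sdt_core import ConfidenceCounts

__all__ = [
    "trials_to_counts",
    "counts_to_trials",
    "bin_confidence_quantiles",
    "bin_table_confidence",
    "read_trials_csv",
    "read_counts_csv",
    "write_counts_csv",
]

_LEVEL_CODES = {"s1": 0, "0": 0, "0.0": 0, "s2": 1, "1": 1, "1.0": 1}
REQUIRED_COLUMNS = ("subject", "stimulus", "response", "confidence")


def _normalize_levels(col: pd.Series, name: str) -> np.ndarray:
    codes = col.astype(str).str.strip().str.lower().map(_LEVEL_CODES)
    if codes.isna().any():
        bad = col[codes.isna()].unique()[:5]
        raise ValueError(f"column {name!r} contains unrecognized codes {list(bad)}; use S1/S2 or 0/1")
    return codes.to_numpy(dtype=np.int64)


def trials_to_counts(table: pd.DataFrame, k: int) -> dict[object, ConfidenceCounts]:
    """Assemble per-subject (nR_S1, nR_S2) count vectors from a trial table.

    ``table`` needs columns subject, stimulus, response, confidence (a
    missing subject column treats all rows as one subject).  Confidence
    must already be integer 1..k.  Returns an ordered mapping from subject
    id to counts; expanding the counts back to trials preserves the joint
    (stimulus, response, confidence) contingency table.
    """
    df = table.copy()
    if "subject" not in df.columns:
        df["subject"] = 0
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns {missing}")
    if df[list(REQUIRED_COLUMNS)].isna().any().any():
        raise ValueError("trial table contains missing cells")
    if len(df) == 0:
        z = np.zeros(2 * k, dtype=np.int64)
        return {0: ConfidenceCounts(nR_S1=z, nR_S2=z.copy())}
    conf = pd.to_numeric(df["confidence"])
    bad = df.index[(conf < 1) | (conf > k) | (conf != conf.round())]
    if len(bad):
        raise ValueError(
            f"confidence outside integers 1..{k} in rows {list(bad[:10])}"
            + (" ..." if len(bad) > 10 else "")
        )
    stim = _normalize_levels(df["stimulus"], "stimulus")
    resp = _normalize_levels(df["response"], "response")
    conf = conf.astype(np.int64).to_numpy()
    # cell index along the evidence-ordered vector: "S1" responses fill
    # cells k-conf, "S2" responses fill cells k-1+conf
    cell = np.where(resp == 0, k - conf, k - 1 + conf)
    out: dict[object, ConfidenceCounts] = {}
    for subj, idx in df.groupby("subject", sort=False).groups.items():
        pos = df.index.get_indexer(idx)
        nR = np.zeros((2, 2 * k), dtype=np.int64)
        for s in (0, 1):
            sel = pos[stim[pos] == s]
            nR[s] = np.bincount(cell[sel], minlength=2 * k)
        out[subj] = ConfidenceCounts(nR_S1=nR[0], nR_S2=nR[1])
    return out


def counts_to_trials(counts: ConfidenceCounts, subject=0) -> pd.DataFrame:
    """Expand count vectors back to one row per trial (inverse of trials_to_counts)."""
    k = counts.k
    rows = []
    for s, vec in ((0, counts.nR_S1), (1, counts.nR_S2)):
        for j, n in enumerate(vec):
            resp = 0 if j < k else 1
            conf = k - j if j < k else j - k + 1
            rows.extend([(subject, s, resp, conf)] * int(n))
    return pd.DataFrame(rows, columns=["subject", "stimulus", "response", "confidence"])


def bin_confidence_quantiles(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin continuous ratings into ``n_bins`` empirical quantiles (1..n_bins).

    Bin edges are the (1/n_bins, ..., (n_bins-1)/n_bins) quantiles of the
    supplied values; a value equal to an edge falls in the lower bin.
    Requires at least ``n_bins`` distinct values.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < n_bins:
        raise ValueError(
            f"fewer than {n_bins} distinct rating values; use fewer bins"
        )
    edges = np.quantile(v, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, v, side="left").astype(np.int64) + 1


def bin_table_confidence(table: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    """Quantile-bin the confidence column separately for each subject.

    Per-subject edges respect each subject's idiosyncratic use of the
    rating scale (pooled edges would mix scales across subjects).
    """
    df = table.copy()
    if "subject" not in df.columns:
        df["subject"] = 0
    df["confidence"] = df.groupby("subject", sort=False)["confidence"].transform(
        lambda s: bin_confidence_quantiles(s.to_numpy(dtype=float), n_bins)
    )
    return df


def read_trials_csv(path, k: int | None = None) -> dict[object, ConfidenceCounts]:
    """Read a trial-level CSV (columns subject,stimulus,response,confidence)."""
    df = pd.read_csv(path)
    if k is None:
        k = int(pd.to_numeric(df["confidence"]).max())
    return trials_to_counts(df, k)


def write_counts_csv(path, counts: dict[object, ConfidenceCounts] | list[ConfidenceCounts]) -> None:
    """One row per subject; columns subject, nR_S1_1..nR_S1_2k, nR_S2_1..nR_S2_2k."""
    if isinstance(counts, list):
        counts = {i: c for i, c in enumerate(counts)}
    ks = {c.k for c in counts.values()}
    if len(ks) != 1:
        raise ValueError("all subjects must share the same number of rating levels")
    k = ks.pop()
    cols = [f"nR_S1_{i + 1}" for i in range(2 * k)] + [f"nR_S2_{i + 1}" for i in range(2 * k)]
    rows = [
        [subj, *c.nR_S1.tolist(), *c.nR_S2.tolist()] for subj, c in counts.items()
    ]
    pd.DataFrame(rows, columns=["subject", *cols]).to_csv(path, index=False)


def read_counts_csv(path) -> dict[object, ConfidenceCounts]:
    """Inverse of :func:`write_counts_csv`."""
    df = pd.read_csv(path)
    s1_cols = sorted(
        (c for c in df.columns if c.startswith("nR_S1_")), key=lambda c: int(c.rsplit("_", 1)[1])
    )
    s2_cols = sorted(
        (c for c in df.columns if c.startswith("nR_S2_")), key=lambda c: int(c.rsplit("_", 1)[1])
    )
    if not s1_cols or len(s1_cols) != len(s2_cols):
        raise ValueError("counts CSV must contain matching nR_S1_* and nR_S2_* columns")
    out = {}
    for _, row in df.iterrows():
        subj = row["subject"] if "subject" in df.columns else len(out)
        out[subj] = ConfidenceCounts(
            nR_S1=row[s1_cols].to_numpy(dtype=np.int64),
            nR_S2=row[s2_cols].to_numpy(dtype=np.int64),
        )
    return out
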