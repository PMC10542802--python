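"""Local constraint scoring of the mitochondrial genome.

The positional score is computed by a sliding-window observed:expected
procedure over a site-frequency database of all possible single-base
substitutions (3 per position).  For every window start (the genome is
circular, so there is one window per position), the observed and expected
substitution counts are summed — restricted to missense changes at
protein-coding positions — and the 90% upper confidence bound of the
observed:expected ratio (OEUF) is taken.  Each position's mean OEUF over
the k windows covering it is percentile-ranked descending to a score in
[0, 1], 1 being most constrained.

Per-variant scores follow the class rule: missense, tRNA, rRNA and
non-coding variants take the positional score; synonymous, stop-gain and
start/stop-loss variants take the fixed class scores 0.0, 1.0 and 0.70.
The per-individual burden (MSS) is the sum of a sample's heteroplasmy
scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .reference import Consequence, GeneMap

# Fixed class scores for non-missense protein variants
SYNONYMOUS_SCORE = 0.0
STOP_GAINED_SCORE = 1.0
START_STOP_LOST_SCORE = 0.70

_ALTS = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


class MissingScoreError(KeyError):
    """Raised when a variant class needs a positional score that is undefined."""


class SiteFrequencyDB:
    """Observed and expected counts for every possible substitution.

    Backed by a DataFrame with columns pos (1-based), ref, alt, observed
    (non-negative int) and expected (positive float): 3 rows per position,
    ``3 * genome_length`` rows in all.
    """

    COLUMNS = ["pos", "ref", "alt", "observed", "expected"]

    def __init__(self, table: pd.DataFrame, genome_length: int):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"site-frequency table missing columns {sorted(missing)}")
        table = table[self.COLUMNS].sort_values(["pos", "alt"]).reset_index(drop=True)
        if len(table) != 3 * genome_length:
            raise ValueError(
                f"expected {3 * genome_length} rows (3 per position), got {len(table)}"
            )
        if (table["expected"] <= 0).any():
            raise ValueError("expected counts must all be positive")
        if (table["observed"] < 0).any():
            raise ValueError("observed counts must be non-negative")
        self.table = table
        self.genome_length = genome_length

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path, genome_length: int) -> "SiteFrequencyDB":
        return cls(pd.read_csv(path, sep="\t"), genome_length)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def missense_inclusion_mask(db: SiteFrequencyDB, genemap: GeneMap) -> np.ndarray:
    """Boolean row mask: which substitutions enter the window sums.

    Protein-coding positions contribute only missense substitutions (a
    change counts as missense if it is missense in any overlapping
    reading frame); all other positions contribute every substitution.
    """
    protein = genemap.protein_positions()
    mask = np.ones(len(db.table), dtype=bool)
    pos_arr = db.table["pos"].to_numpy()
    alt_arr = db.table["alt"].to_numpy()
    protein_feats = [f for f in genemap.features if f.product_class == "protein"]
    for i, (pos, alt) in enumerate(zip(pos_arr, alt_arr)):
        if pos not in protein:
            continue
        feats = [f for f in protein_feats if f.contains(pos)]
        mask[i] = any(
            genemap._protein_consequence(f, int(pos), alt).kind == "missense"
            for f in feats
        )
    return mask


def _poisson_upper(n: np.ndarray, ci_level: float, method: str) -> np.ndarray:
    """Upper CI bound for a Poisson mean given ``n`` observed events."""
    alpha = 1.0 - ci_level
    if method == "garwood":
        return stats.chi2.ppf(1 - alpha / 2, 2 * n + 2) / 2.0
    if method == "profile":
        crit = stats.chi2.ppf(ci_level, 1)

        def upper_one(k: float) -> float:
            def f(mu):
                loglik = -mu + (k * np.log(mu) if k > 0 else 0.0)
                loglik_hat = -k + (k * np.log(k) if k > 0 else 0.0)
                return 2 * (loglik_hat - loglik) - crit

            hi = max(k, 1.0)
            while f(hi) < 0:
                hi *= 2
            return brentq(f, max(k, 1e-12), hi)

        return np.array([upper_one(float(k)) for k in np.atleast_1d(n)])
    raise ValueError(f"unknown CI method {method!r}")


def _circular_window_sums(values: np.ndarray, k: int) -> np.ndarray:
    """Sum of ``values[start:start+k]`` for every start, with wraparound."""
    n = len(values)
    tiled = np.concatenate([values, values[: k - 1]]) if k > 1 else values
    csum = np.concatenate([[0.0], np.cumsum(tiled)])
    return csum[k:k + n] - csum[:n]


def window_oe(
    db: SiteFrequencyDB,
    genemap: GeneMap | None = None,
    k: int = 30,
    ci_level: float = 0.90,
    include: np.ndarray | None = None,
    ci_method: str = "garwood",
) -> pd.DataFrame:
    """Observed:expected ratio and OEUF for every circular window.

    Returns one row per start position 1..genome_length with columns
    start, k, n_obs, sum_exp, oe, oeuf and flagged (True when the window
    has zero total expected count, leaving oe undefined).

    ``include`` overrides the missense-only inclusion mask (useful for toy
    genomes without an annotation); with ``genemap=None`` and no mask,
    every substitution is included.
    """
    if k < 1:
        raise ValueError("window length k must be >= 1")
    if include is None:
        if genemap is not None:
            include = missense_inclusion_mask(db, genemap)
        else:
            include = np.ones(len(db.table), dtype=bool)

    table = db.table
    n = db.genome_length
    obs_by_pos = np.zeros(n)
    exp_by_pos = np.zeros(n)
    idx = table["pos"].to_numpy() - 1
    np.add.at(obs_by_pos, idx[include], table["observed"].to_numpy()[include])
    np.add.at(exp_by_pos, idx[include], table["expected"].to_numpy()[include])

    win_obs = _circular_window_sums(obs_by_pos, k)
    win_exp = _circular_window_sums(exp_by_pos, k)

    flagged = win_exp <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(flagged, np.nan, win_obs / np.where(flagged, 1.0, win_exp))
        upper_count = _poisson_upper(np.round(win_obs).astype(int), ci_level, ci_method)
        oeuf = np.where(flagged, np.nan, upper_count / np.where(flagged, 1.0, win_exp))

    return pd.DataFrame(
        {
            "start": np.arange(1, n + 1),
            "k": k,
            "n_obs": win_obs,
            "sum_exp": win_exp,
            "oe": oe,
            "oeuf": oeuf,
            "flagged": flagged,
        }
    )


@dataclass
class MLCTrack:
    """Per-position mean OEUF and percentile-ranked positional score."""

    table: pd.DataFrame  # columns: pos, mean_oeuf, positional_score
    k: int

    def score(self, pos: int) -> float:
        row = self.table.iloc[pos - 1]
        assert int(row["pos"]) == pos
        return float(row["positional_score"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_bed(self, path, name: str = "mlc") -> None:
        """BED-like track: chrom, 0-based start, end, score."""
        with open(path, "w") as fh:
            for _, row in self.table.iterrows():
                p = int(row["pos"])
                fh.write(f"chrM\t{p - 1}\t{p}\t{row['positional_score']:.6g}\n")


def _descending_percentile(values: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Fractional-rank percentile, descending: max -> 0, min -> 1, ties share.

    Values closer than ``tol`` (relative) are treated as tied so that
    running-sum rounding noise cannot split a genuine tie group.
    """
    out = np.full(len(values), np.nan)
    ok = ~np.isnan(values)
    m = int(ok.sum())
    if m == 0:
        return out
    if m == 1:
        out[ok] = 0.5
        return out
    vals = values[ok]
    order = np.argsort(-vals, kind="stable")
    sorted_vals = vals[order]
    ranks = np.empty(m)
    i = 0
    while i < m:
        j = i + 1
        while j < m and (sorted_vals[j - 1] - sorted_vals[j]) <= tol * (
            1.0 + abs(sorted_vals[j])
        ):
            j += 1
        ranks[order[i:j]] = (i + 1 + j) / 2.0  # mean of ranks i+1 .. j
        i = j
    out[ok] = (ranks - 1) / (m - 1)
    return out


def positional_scores(windows: pd.DataFrame, k: int | None = None) -> MLCTrack:
    """Collapse window OEUFs to per-position mean OEUF and percentile score.

    Each position is covered by exactly the k windows whose start lies in
    the k positions ending at it (circularly).  Flagged windows are
    excluded from the mean; positions covered only by flagged windows get
    an undefined (NaN) score.
    """
    if k is None:
        k = int(windows["k"].iloc[0])
    n = len(windows)
    oeuf = windows.sort_values("start")["oeuf"].to_numpy()
    valid = ~np.isnan(oeuf)

    # position p (1-based) is covered by windows starting at p-k+1 .. p;
    # the forward window sum starting at p-k+1 is exactly that, so a roll
    # by k-1 turns start-anchored sums into coverage sums
    sums = np.roll(_circular_window_sums(np.where(valid, oeuf, 0.0), k), k - 1)
    counts = np.roll(_circular_window_sums(valid.astype(float), k), k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_oeuf = np.where(counts > 0, sums / counts, np.nan)

    score = _descending_percentile(mean_oeuf)
    table = pd.DataFrame(
        {"pos": np.arange(1, n + 1), "mean_oeuf": mean_oeuf, "positional_score": score}
    )
    return MLCTrack(table=table, k=k)


def variant_mlc(consequence: Consequence, track: MLCTrack, pos: int) -> float:
    """MLC score of one substitution under the class rule."""
    kind = consequence.kind
    if kind == "synonymous":
        return SYNONYMOUS_SCORE
    if kind == "stop_gained":
        return STOP_GAINED_SCORE
    if kind in ("start_lost", "stop_lost"):
        return START_STOP_LOST_SCORE
    if kind in ("missense", "tRNA", "rRNA", "noncoding"):
        value = track.score(pos)
        if np.isnan(value):
            raise MissingScoreError(
                f"positional score undefined at m.{pos} for a {kind} variant"
            )
        return value
    raise ValueError(f"unknown consequence kind {kind!r}")


@dataclass(frozen=True)
class MSSValue:
    """Per-individual MLC score sum."""

    sample_id: str
    mss: float
    n_heteroplasmies: int


def mss(sample_id: str, mlc_scores) -> MSSValue:
    """Sum a sample's heteroplasmy MLC scores (empty -> 0.0)."""
    scores = list(mlc_scores)
    for s in scores:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"MLC score {s} outside [0, 1] for sample {sample_id}")
    return MSSValue(sample_id=sample_id, mss=float(sum(scores)),
                    n_heteroplasmies=len(scores))
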