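"""Survey-level statistics: type enrichment, region-length permutation test,
0.1-binned distributions and the per-case summary table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import InvalidInputError


def type_enrichment_test(n_type_c: int, n_type_n: int) -> float:
    """Exact two-sided binomial test of the C/N split against p = 1/2.

    Two-sided by doubling the smaller tail, capped at 1.
    """
    if n_type_c < 0 or n_type_n < 0:
        raise InvalidInputError("counts must be non-negative")
    n = n_type_c + n_type_n
    if n < 1:
        raise InvalidInputError("need at least one case")
    k = n_type_c
    lower = sps.binom.cdf(k, n, 0.5)
    upper = sps.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def region_length_permutation_test(
    fs_lengths,
    of_lengths,
    n_perm: int = 10_000,
    seed: int = 0,
    variant: str = "paired",
) -> float:
    """Paired sign-flip permutation test that frameshifted regions are shorter.

    The statistic is the mean per-case difference (frameshifted minus
    original-frame relative length); each permutation flips each difference's
    sign with probability 1/2.  One-sided p = proportion of permuted means
    <= the observed mean, with the observed permutation included (add-one).
    ``variant="pooled"`` instead permutes region labels across the pooled
    values.
    """
    fs = np.asarray(fs_lengths, dtype=float)
    of = np.asarray(of_lengths, dtype=float)
    if fs.shape != of.shape or fs.ndim != 1 or len(fs) < 2:
        raise InvalidInputError("paired lists of equal length >= 2 required")
    if n_perm < 100:
        raise InvalidInputError("n_perm < 100 gives an unstable p-value")
    rng = np.random.default_rng(seed)
    if variant == "paired":
        diffs = fs - of
        obs = diffs.mean()
        signs = rng.integers(0, 2, size=(n_perm, len(diffs))) * 2 - 1
        perm = (signs * diffs).mean(axis=1)
    elif variant == "pooled":
        pooled = np.concatenate([fs, of])
        obs = fs.mean() - of.mean()
        perm = np.empty(n_perm)
        for k in range(n_perm):
            idx = rng.permutation(len(pooled))
            perm[k] = pooled[idx[: len(fs)]].mean() - pooled[idx[len(fs) :]].mean()
    else:
        raise InvalidInputError("variant must be 'paired' or 'pooled'")
    return float((1 + np.sum(perm <= obs)) / (n_perm + 1))


def bin_distribution(values, lo: float = 0.0, hi: float = 1.0):
    """Histogram with exact width-0.1 bins over [lo, hi]; last bin closed.

    Returns ``(edges, counts)``.  Out-of-range values are an error.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size:
        bad = vals[(vals < lo) | (vals > hi)]
        if bad.size:
            raise InvalidInputError(f"value {bad[0]} outside [{lo}, {hi}]")
    edges = lo + (hi - lo) * np.linspace(0.0, 1.0, 11)
    counts, _ = np.histogram(vals, bins=edges)
    return edges, counts


@dataclass
class SurveySummary:
    n_cases: int
    n_single_event: int
    n_multi_event: int
    type_counts: dict[str, int]
    location_histogram: tuple
    length_histogram: tuple
    ks_c_histogram: tuple
    ratio_histogram: tuple
    test_results: dict[str, float] = field(default_factory=dict)

    def to_key_values(self) -> dict[str, object]:
        out: dict[str, object] = {
            "n_cases": self.n_cases,
            "n_single_event": self.n_single_event,
            "n_multi_event": self.n_multi_event,
        }
        for t, c in sorted(self.type_counts.items()):
            out[f"type_count_{t}"] = c
        for name in ("location", "length", "ks_c", "ratio"):
            _, counts = getattr(self, f"{name}_histogram")
            out[f"{name}_histogram"] = ",".join(str(int(c)) for c in counts)
        out.update(self.test_results)
        return out


def summarize_survey(
    cases: pd.DataFrame,
    kaks: pd.DataFrame | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> SurveySummary:
    """Headline tallies, 0.1-binned distributions and survey-level tests.

    ``cases`` is the per-case table produced by the pipeline (columns
    ``type``, ``n_events``, ``relative_location``, ``relative_fs_length``,
    ``relative_of_length``, ``ks_c``, ``ka_c``).
    """
    n_cases = len(cases)
    n_single = int((cases["n_events"] == 1).sum()) if n_cases else 0
    type_counts = cases["type"].value_counts().to_dict() if n_cases else {}
    loc = cases["relative_location"].dropna() if n_cases else []
    flen = cases["relative_fs_length"].dropna() if n_cases else []
    ks_vals, ratio_vals = [], []
    if n_cases and "ks_c" in cases:
        ks_vals = [v for v in cases["ks_c"].dropna() if 0 <= v <= 1]
    if n_cases and {"ks_c", "ka_c"} <= set(cases.columns):
        sub = cases.dropna(subset=["ks_c", "ka_c"])
        ratios = [a / s for a, s in zip(sub["ka_c"], sub["ks_c"]) if s > 0]
        ratio_vals = [r for r in ratios if 0 <= r <= 1]
    tests: dict[str, float] = {}
    singles = cases[cases["n_events"] == 1] if n_cases else cases
    n_c = int((singles["type"] == "C").sum()) if n_cases else 0
    n_n = int((singles["type"] == "N").sum()) if n_cases else 0
    if n_c + n_n >= 1:
        tests["binomial_p_c_vs_n"] = type_enrichment_test(n_c, n_n)
    for t in ("C", "N"):
        sub = cases[cases["type"] == t] if n_cases else cases
        if len(sub) >= 2:
            tests[f"permutation_p_{t}"] = region_length_permutation_test(
                sub["relative_fs_length"].to_numpy(),
                sub["relative_of_length"].to_numpy(),
                n_perm=n_perm,
                seed=seed,
            )
    return SurveySummary(
        n_cases=n_cases,
        n_single_event=n_single,
        n_multi_event=n_cases - n_single,
        type_counts=type_counts,
        location_histogram=bin_distribution(loc),
        length_histogram=bin_distribution(flen),
        ks_c_histogram=bin_distribution(ks_vals),
        ratio_histogram=bin_distribution(ratio_vals),
        test_results=tests,
    )
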