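"""Community-level statistics over spacer-group repertoires.

Covers the between-subject sharing spectrum, a permutation test for
subject specificity of DNA/cDNA repertoires, richness rarefaction by
repeated subsampling, Welch comparisons of shared-fraction means, and the
dense group-by-sample abundance matrix behind heatmap figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SharedFraction",
    "shared_fraction",
    "sharing_spectrum",
    "PermutationResult",
    "subject_specificity_test",
    "rarefaction_curve",
    "heatmap_matrix",
    "compare_group_means",
]


@dataclass(frozen=True)
class SharedFraction:
    directional: float  # |A n B| / |A|
    symmetric: float  # Jaccard: |A n B| / |A u B|


def shared_fraction(a: set, b: set) -> SharedFraction:
    """Fraction of A's spacer groups also present in B (plus Jaccard)."""
    if not a:
        raise ValueError("shared fraction undefined for an empty reference set")
    inter = len(a & b)
    union = len(a | b)
    return SharedFraction(directional=inter / len(a), symmetric=inter / union)


def sharing_spectrum(
    subjects: Mapping[str, set], strata: Mapping[str, str]
) -> pd.DataFrame:
    """Percentage of spacer groups present in exactly k subjects.

    Index: k = 1..n_subjects.  Columns (each summing to 100 over k where
    non-empty):

    * ``all`` — every group, k = incidence among all subjects;
    * ``healthy`` / ``disease`` — groups seen in that stratum, k = incidence
      among that stratum's subjects only;
    * ``cross`` — groups seen in at least one healthy and one disease
      subject, k = incidence among all subjects.
    """
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects for a sharing spectrum")
    labels = list(subjects)
    n = len(labels)
    healthy = [s for s in labels if strata.get(s) == "healthy"]
    disease = [s for s in labels if strata.get(s) == "disease"]

    def spectrum(members: Sequence[str], restrict_to: Optional[set] = None) -> np.ndarray:
        incidence: dict[Hashable, int] = {}
        present: dict[Hashable, set] = {}
        for s in labels:
            for g in subjects[s]:
                present.setdefault(g, set()).add(s)
        counts = np.zeros(n, dtype=float)
        member_set = set(members)
        for g, where in present.items():
            if not (where & member_set):
                continue
            if restrict_to is not None and not (where & restrict_to[0] and where & restrict_to[1]):
                continue
            k = len(where & member_set) if restrict_to is None else len(where)
            counts[k - 1] += 1
        total = counts.sum()
        return 100.0 * counts / total if total else counts

    data = {
        "all": spectrum(labels),
        "healthy": spectrum(healthy),
        "disease": spectrum(disease),
        "cross": spectrum(labels, restrict_to=(set(healthy), set(disease))),
    }
    return pd.DataFrame(data, index=pd.RangeIndex(1, n + 1, name="n_subjects_sharing"))


@dataclass
class PermutationResult:
    observed: float
    null_samples: np.ndarray
    n_iterations: int
    groups_per_iteration: int
    sampled_with_replacement: bool = False
    mode: str = "conditional"

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_samples))

    @property
    def p_value(self) -> float:
        # fraction of null samples at least as extreme as the observation;
        # 0 means "below the test's 1/n_iterations resolution"
        if self.mode == "literal":
            return float(np.mean(self.null_samples))
        return float(np.mean(self.null_samples >= self.observed))


def _random_subsets(
    rng: np.random.Generator, n_universe: int, size: int, n_iter: int, replace: bool
) -> np.ndarray:
    """(n_iter, size) index matrix of random subsets of range(n_universe)."""
    if replace:
        return rng.integers(0, n_universe, size=(n_iter, size))
    u = rng.random((n_iter, n_universe))
    return np.argpartition(u, size - 1, axis=1)[:, :size]


def subject_specificity_test(
    subject_sets: Mapping[str, Mapping[str, set]],
    subject: str,
    n_iterations: int = 10_000,
    groups_per_iteration: int = 1_000,
    seed: Optional[int] = None,
    mode: Literal["conditional", "literal"] = "conditional",
    universe: Optional[Iterable[Hashable]] = None,
) -> PermutationResult:
    """Permutation test: is a subject's DNA/cDNA overlap subject specific?

    ``subject_sets`` maps each subject label to {"DNA": set, "cDNA": set}.
    The observed statistic is the intra-subject shared fraction
    |DNA n cDNA| / |DNA|.  Each null iteration draws two random group sets
    of the observed sizes (capped at ``groups_per_iteration``; sampling
    switches to with-replacement, and is flagged, if the cap exceeds the
    universe) from the group universe (default: the union over all
    subjects and fractions) and recomputes the statistic; the p-value is
    the fraction of null draws at least as large as the observation.

    ``mode="literal"`` instead records, per iteration, whether a simulated
    intra-subject statistic (subsets of the subject's own repertoire)
    exceeds a simulated inter-subject statistic (subject vs the rest), and
    reports the exceedance fraction as the p-value — a direct transcription
    of the published wording, under which *small* values indicate a lack of
    subject specificity.
    """
    sets = subject_sets[subject]
    A, B = set(sets["DNA"]), set(sets["cDNA"])
    if not A or not B:
        raise ValueError(f"subject {subject!r} needs non-empty DNA and cDNA sets")
    if universe is None:
        pool: set = set()
        for s in subject_sets.values():
            for frac_set in s.values():
                pool |= set(frac_set)
    else:
        pool = set(universe)
    pool_list = sorted(pool, key=repr)
    U = len(pool_list)
    index = {g: i for i, g in enumerate(pool_list)}
    rng = np.random.default_rng(seed)

    observed = len(A & B) / len(A)
    nA = min(len(A), groups_per_iteration)
    nB = min(len(B), groups_per_iteration)
    replace = groups_per_iteration > U and (len(A) > U or len(B) > U)

    if mode == "conditional":
        a_idx = _random_subsets(rng, U, nA, n_iterations, replace)
        b_idx = _random_subsets(rng, U, nB, n_iterations, replace)
        null = _overlap_fraction(a_idx, b_idx, U)
    else:
        # literal reading: intra-subject draws come from the subject's own
        # pooled repertoire, inter-subject draws pit the subject against
        # everyone else's groups
        own = sorted(A | B, key=repr)
        others = sorted(pool - (A | B), key=repr) or pool_list
        n_own = len(own)
        nA_o = min(nA, n_own)
        nB_o = min(nB, n_own)
        intra_a = _random_subsets(rng, n_own, nA_o, n_iterations, replace)
        intra_b = _random_subsets(rng, n_own, nB_o, n_iterations, replace)
        intra = _overlap_fraction(intra_a, intra_b, n_own)
        n_oth = len(others)
        inter_a = _random_subsets(rng, n_own, nA_o, n_iterations, replace)
        inter_b_local = _random_subsets(rng, n_oth, min(nB, n_oth), n_iterations, replace)
        # map both to the shared universe for the overlap count
        own_ids = np.array([index[g] for g in own])
        oth_ids = np.array([index[g] for g in others])
        inter = _overlap_fraction(own_ids[inter_a], oth_ids[inter_b_local], U)
        null = (intra > inter).astype(float)

    return PermutationResult(
        observed=observed,
        null_samples=null,
        n_iterations=n_iterations,
        groups_per_iteration=groups_per_iteration,
        sampled_with_replacement=replace,
        mode=mode,
    )


def _overlap_fraction(a_idx: np.ndarray, b_idx: np.ndarray, n_universe: int) -> np.ndarray:
    """Row-wise |A n B| / |A| for index-matrix subsets of a shared universe."""
    n_iter = a_idx.shape[0]
    member = np.zeros((n_iter, n_universe), dtype=bool)
    rows = np.repeat(np.arange(n_iter), a_idx.shape[1])
    member[rows, a_idx.ravel()] = True
    hits = member[np.repeat(np.arange(n_iter), b_idx.shape[1]), b_idx.ravel()]
    inter = hits.reshape(n_iter, b_idx.shape[1]).sum(axis=1)
    return inter / a_idx.shape[1]


def rarefaction_curve(
    sample: Mapping[Hashable, int],
    depths: Sequence[int],
    iterations: int = 10_000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Mean (+/- SD) distinct-group richness at reduced sampling depths.

    Subsamples the observed count vector without replacement ``iterations``
    times; one permutation per iteration serves every depth (richness at
    depth d is the number of groups first seen within the first d draws).
    """
    counts = {k: int(v) for k, v in sample.items() if v > 0}
    total = sum(counts.values())
    depths = sorted(int(d) for d in depths)
    if not depths or depths[0] < 1:
        raise ValueError("depths must be positive")
    if depths[-1] > total:
        raise ValueError(f"depth {depths[-1]} exceeds total count {total}")
    keys = sorted(counts, key=repr)
    pool = np.repeat(np.arange(len(keys)), [counts[k] for k in keys])
    rng = np.random.default_rng(seed)
    rich = np.zeros((iterations, len(depths)))
    for it in range(iterations):
        perm = rng.permutation(pool)
        first = np.sort(np.unique(perm, return_index=True)[1])
        rich[it] = np.searchsorted(first, depths, side="left")
    return pd.DataFrame(
        {
            "depth": depths,
            "mean_richness": rich.mean(axis=0),
            "sd_richness": rich.std(axis=0),
        }
    )


def heatmap_matrix(
    subjects: Mapping[str, Mapping[str, Mapping[Hashable, float]]]
) -> pd.DataFrame:
    """Dense groups x (subject, fraction) abundance matrix.

    For each subject the DNA column precedes the cDNA column; rows are
    ordered by total abundance (descending, ties by group id) so dominant
    groups sit at the top, matching the usual heatmap layout.
    """
    if not subjects:
        raise ValueError("need >= 1 subject")
    columns = []
    for label in subjects:
        for frac in ("DNA", "cDNA"):
            if frac in subjects[label]:
                columns.append((label, frac))
    all_groups = sorted(
        {g for label, fracs in subjects.items() for m in fracs.values() for g in m},
        key=repr,
    )
    data = {
        f"{label}:{frac}": [float(subjects[label][frac].get(g, 0.0)) for g in all_groups]
        for label, frac in columns
    }
    df = pd.DataFrame(data, index=pd.Index(all_groups, name="group_id"))
    order = df.sum(axis=1).sort_values(ascending=False, kind="stable").index
    return df.loc[order]


def compare_group_means(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Welch two-tailed t-test on two lists of per-subject shared fractions.

    Returns (t, p).  Two zero-variance samples with equal means give
    (0.0, 1.0) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.var(x) == 0 and np.var(y) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float("inf") if x.mean() > y.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
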