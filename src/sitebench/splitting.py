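"""Cross-validation fold construction.

Two designs with opposite leakage profiles:

- *Splitting by Age/Sex*: every cohort is spread across all folds with
  balanced age, sex and diagnosis — measures in-distribution separability.
- *Splitting by Site*: whole cohorts are packed into single folds — measures
  generalization to sites never seen in training.

Leave-one-site-out assignments are provided for per-site evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .rng import substream


@dataclass
class FoldAssignment:
    """Partition of subjects into k folds."""

    strategy: str                 # age_sex | site | loso
    k: int
    fold_of: dict                 # subject_id -> fold index in [1..k]
    dropped: list = field(default_factory=list)  # (subject_id, reason)
    test_site: str | None = None  # set for loso assignments

    @property
    def subjects(self) -> list:
        return list(self.fold_of)

    def fold_members(self, fold: int) -> list:
        return [s for s, f in self.fold_of.items() if f == fold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": list(self.fold_of),
            "strategy": self.strategy,
            "fold": list(self.fold_of.values()),
        })


def split_by_age_sex(roster: pd.DataFrame, k: int = 10,
                     seed: int = 0) -> FoldAssignment:
    """Balanced folds: every cohort is spread across all k folds with
    (dx, sex) strata dealt evenly and fold age means kept close to the
    cohort mean.

    Within each cohort and (dx, sex) stratum, subjects are processed oldest
    first; each goes to a stratum-balanced fold (minimal count from that
    stratum) whose updated mean age deviates least from the cohort mean.
    The fold preference order is a seeded permutation, so ties break
    reproducibly but differently across seeds. Cohorts with fewer than k
    subjects are dropped from the assignment (they cannot appear in every
    fold).
    """
    if k < 2:
        raise ConfigError("k must be >= 2")
    if len(roster) < k:
        raise ConfigError(f"fewer than k={k} subjects in roster")
    rng = substream(seed, "split-age-sex")
    fold_of: dict = {}
    dropped: list = []
    for site, group in roster.groupby("site", sort=True):
        if len(group) < k:
            for sid in group["subject_id"]:
                dropped.append((sid, f"cohort {site} has fewer than {k} subjects"))
            continue
        target = group["age"].mean()
        count = np.zeros(k, dtype=int)
        age_sum = np.zeros(k)
        order = rng.permutation(k)
        for (_, _), stratum in group.groupby(["dx", "sex"], sort=True):
            s_count = np.zeros(k, dtype=int)
            ordered = stratum.sort_values(["age", "subject_id"],
                                          ascending=[False, True])
            for sid, age in zip(ordered["subject_id"], ordered["age"]):
                m = s_count.min()
                elig = s_count == m
                # keep total fold sizes tight (one subject of slack buys a
                # much better age balance)
                elig &= count <= count[elig].min() + 1
                best, best_dev = None, None
                for f in order:
                    if not elig[f]:
                        continue
                    dev = abs((age_sum[f] + age) / (count[f] + 1) - target)
                    if best_dev is None or dev < best_dev - 1e-12:
                        best, best_dev = f, dev
                fold_of[sid] = int(best) + 1
                s_count[best] += 1
                count[best] += 1
                age_sum[best] += age
    if not fold_of:
        raise ConfigError("no cohort large enough for the requested k")
    return FoldAssignment("age_sex", k, fold_of, dropped)


def split_by_site(roster: pd.DataFrame, k: int = 10) -> FoldAssignment:
    """Whole-cohort folds via deterministic greedy bin packing.

    Sites are sorted by size descending (name as tie-break) and assigned,
    one at a time, to the currently smallest fold.
    """
    if k < 2:
        raise ConfigError("k must be >= 2")
    sizes = roster.groupby("site").size()
    if len(sizes) < k:
        raise ConfigError(
            f"only {len(sizes)} sites for k={k} folds; lower k to at most "
            f"{len(sizes)}")
    order = sorted(sizes.items(), key=lambda it: (-it[1], it[0]))
    load = np.zeros(k, dtype=int)
    site_fold: dict = {}
    for site, n in order:
        fold = int(np.argmin(load))   # first smallest fold wins ties
        site_fold[site] = fold + 1
        load[fold] += n
    fold_of = {sid: site_fold[site]
               for sid, site in zip(roster["subject_id"], roster["site"])}
    return FoldAssignment("site", k, fold_of)


def leave_one_site_out(roster: pd.DataFrame) -> list[FoldAssignment]:
    """One assignment per site: fold 1 = all other sites, fold 2 = the site."""
    sites = sorted(roster["site"].unique())
    if len(sites) < 2:
        raise ConfigError("leave-one-site-out requires at least 2 sites")
    out = []
    for site in sites:
        fold_of = {sid: (2 if s == site else 1)
                   for sid, s in zip(roster["subject_id"], roster["site"])}
        out.append(FoldAssignment("loso", 2, fold_of, test_site=site))
    return out


def fold_balance_report(assignment: FoldAssignment,
                        roster: pd.DataFrame) -> pd.DataFrame:
    """Per-fold demographics: n, age mean/sd, females, %MDD."""
    r = roster.set_index("subject_id")
    rows = []
    for fold in range(1, assignment.k + 1):
        members = assignment.fold_members(fold)
        g = r.loc[members]
        n_female = int((g["sex"] == "F").sum())
        rows.append({
            "fold": fold,
            "n": len(g),
            "age_mean": float(g["age"].mean()) if len(g) else float("nan"),
            "age_sd": float(g["age"].std(ddof=1)) if len(g) > 1 else 0.0,
            "n_female": n_female,
            "pct_female": 100.0 * n_female / len(g) if len(g) else float("nan"),
            "pct_mdd": (100.0 * (g["dx"] == "MDD").mean()) if len(g) else float("nan"),
        })
    return pd.DataFrame(rows)
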