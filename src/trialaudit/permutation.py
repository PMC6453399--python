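"""Permutation validity audit for trial statistics.

If an analysis pipeline is statistically sound, rerunning it after randomly
reassigning the yes/no trial labels should (almost) never find anything:
under permutation the two label groups are exchangeable by construction.
A procedure that keeps declaring significance on permuted labels is
understating its variance — the signature of treating correlated channels
as independent replicates.

The audit reruns collapse + timepoint-wise t-tests on ``n_perm`` independent
label permutations and reports how many permutations produced at least one
timepoint below ``audit_alpha`` (default 0.0005, the display threshold the
flawed analysis is examined at).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .averaging import AveragingSpec, collapse, timepoint_ttest
from .data import DayRecord, SessionRecord, TrialDataset


def _permute_session(
    sess: SessionRecord, rng: np.random.Generator
) -> SessionRecord:
    n_yes, n_no = sess.trials_yes.shape[0], sess.trials_no.shape[0]
    if n_yes == 0 or n_no == 0:
        return sess  # nothing to exchange; return unchanged
    pool = np.concatenate([sess.trials_yes, sess.trials_no], axis=0)
    order = rng.permutation(n_yes + n_no)
    return SessionRecord(
        session_id=sess.session_id,
        trials_yes=pool[order[:n_yes]],
        trials_no=pool[order[n_yes:]],
    )


def permute_labels(
    dataset: TrialDataset,
    seed: int | list[int] | np.random.SeedSequence | np.random.Generator,
    scope: str = "session",
) -> TrialDataset:
    """Randomly reassign trials to conditions, preserving per-condition counts.

    ``scope="session"`` (default) permutes within each session — the
    conservative choice that respects session-level exchangeability.
    ``scope="global"`` pools all trials of the dataset before redistributing
    them to the original per-session per-condition slots.

    Signal values are untouched; only the condition assignment changes.
    Deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if scope == "session":
        days = [
            DayRecord(
                day_id=day.day_id,
                sessions=[_permute_session(s, rng) for s in day.sessions],
            )
            for day in dataset.days
        ]
    elif scope == "global":
        pool = np.concatenate(
            [s.trials(c) for _, s in dataset.iter_sessions() for c in ("yes", "no")],
            axis=0,
        )
        order = rng.permutation(pool.shape[0])
        pos = 0
        days = []
        for day in dataset.days:
            sessions = []
            for s in day.sessions:
                n_yes, n_no = s.trials_yes.shape[0], s.trials_no.shape[0]
                take = order[pos : pos + n_yes + n_no]
                pos += n_yes + n_no
                sessions.append(
                    SessionRecord(
                        session_id=s.session_id,
                        trials_yes=pool[take[:n_yes]],
                        trials_no=pool[take[n_yes:]],
                    )
                )
            days.append(DayRecord(day_id=day.day_id, sessions=sessions))
    else:
        raise ValueError(f"unknown scope {scope!r}; expected 'session' or 'global'")
    return TrialDataset(
        patient_id=dataset.patient_id,
        days=days,
        n_channels=dataset.n_channels,
        time_axis=dataset.time_axis,
        sampling_rate=dataset.sampling_rate,
    )


@dataclass
class PermutationAuditResult:
    """Outcome of rerunning a procedure on label-permuted data."""

    method: str
    n_permutations: int
    significant_counts: np.ndarray  # per-permutation count of timepoints < audit_alpha
    flagged: np.ndarray  # per-permutation: any timepoint significant?
    audit_alpha: float
    seed: int
    scope: str = "session"

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def fraction_flagged(self) -> float:
        if self.n_permutations == 0:
            return float("nan")
        return self.n_flagged / self.n_permutations

    def summary(self) -> str:
        frac = "n/a" if self.n_permutations == 0 else f"{self.fraction_flagged:.2f}"
        verdict = (
            "procedure FAILS the permutation audit (finds effects in noise)"
            if self.n_permutations > 0 and self.fraction_flagged > 0.5
            else "procedure passes the permutation audit"
        )
        return (
            "Permutation validity audit\n"
            "==========================\n"
            f"method = {self.method}, scope = {self.scope}, audit alpha = {self.audit_alpha:g}\n"
            f"permutations flagged: {self.n_flagged}/{self.n_permutations} ({frac})\n"
            f"{verdict}"
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "method": self.method,
            "scope": self.scope,
            "n_permutations": self.n_permutations,
            "audit_alpha": self.audit_alpha,
            "seed": self.seed,
            "significant_counts": [int(c) for c in self.significant_counts],
            "flagged": [bool(f) for f in self.flagged],
            "n_flagged": self.n_flagged,
            "fraction_flagged": None
            if self.n_permutations == 0
            else self.fraction_flagged,
        }


def audit(
    dataset: TrialDataset,
    spec: AveragingSpec,
    n_perm: int = 10,
    audit_alpha: float = 0.0005,
    seed: int = 0,
    scope: str = "session",
    paired: bool = False,
) -> PermutationAuditResult:
    """Rerun collapse + t-test on ``n_perm`` label permutations.

    A permutation is *flagged* when at least one timepoint has an
    uncorrected p below ``audit_alpha``.  Permutation ``i`` uses the
    derived seed ``(seed, i)``, so results are reproducible and individual
    permutations are re-runnable in isolation.
    """
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    counts = np.zeros(n_perm, dtype=int)
    flagged = np.zeros(n_perm, dtype=bool)
    for i in range(n_perm):
        permuted = permute_labels(dataset, [seed, i], scope=scope)
        curve = timepoint_ttest(collapse(permuted, spec), paired=paired, alpha=audit_alpha)
        counts[i] = int((curve.p < audit_alpha).sum())
        flagged[i] = counts[i] > 0
    return PermutationAuditResult(
        method=spec.label or "+".join(spec.order),
        n_permutations=n_perm,
        significant_counts=counts,
        flagged=flagged,
        audit_alpha=audit_alpha,
        seed=seed,
        scope=scope,
    )


class PermutationAudit:
    """Model-style front end for the permutation validity audit.

    >>> res = PermutationAudit(dataset, METHOD_A, n_perm=10, seed=7).fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        dataset: TrialDataset,
        spec: AveragingSpec | str,
        n_perm: int = 10,
        audit_alpha: float = 0.0005,
        seed: int = 0,
        scope: str = "session",
    ) -> None:
        self.dataset = dataset
        self.spec = AveragingSpec.from_label(spec) if isinstance(spec, str) else spec
        self.n_perm = n_perm
        self.audit_alpha = audit_alpha
        self.seed = seed
        self.scope = scope

    def fit(self) -> PermutationAuditResult:
        return audit(
            self.dataset,
            self.spec,
            n_perm=self.n_perm,
            audit_alpha=self.audit_alpha,
            seed=self.seed,
            scope=self.scope,
        )
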