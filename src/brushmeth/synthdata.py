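"""Synthetic panels, methylation profiles, bisulfite reads and cohorts.

Everything here is seed-deterministic (``numpy.random.default_rng``) so the
whole pipeline can be exercised without any external data. Only the
bisulfite-converted top strand is simulated and every read covers its full
amplicon (locus-specific amplicon products); read ids carry ground truth as
``"<gene>|<index>"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, FACTOR_LEVELS, validate_cohort
from .fastqio import FastqRecord
from .panel import DEFAULT_GENES, Amplicon, AmpliconPanel

CLASS_LABELS = ("tumor", "healthy", "regenerative")

#: Class-conditional Beta(alpha, beta) parameters for per-CpG methylation
#: levels. Free simulator knobs, not estimates of any real cohort.
DEFAULT_BETA_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "tumor": {"informative": (8.0, 2.0), "background": (1.5, 10.0)},
    "regenerative": {"informative": (6.0, 2.0), "background": (1.5, 10.0)},
    "healthy": {"informative": (1.5, 10.0), "background": (1.5, 10.0)},
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PackingError(ValueError):
    """Requested CpG count cannot be placed in the amplicon length."""


@dataclass(frozen=True)
class MethylationProfile:
    """Per-sample ground-truth methylation levels, one per CpG id."""

    sample_id: str
    class_label: str
    levels: dict[str, float]

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        for cid, m in self.levels.items():
            if not (0.0 <= m <= 1.0):
                raise ValueError(f"{cid}: level {m} outside [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated follow-up cohort.

    Relapse hazard is exponential at ``baseline_hazard`` events/month,
    multiplied by ``hazard_ratio_positive`` for score-positive patients and
    by ``covariate_hazard_ratios[factor]`` for each listed binary factor at
    its "Yes" level. Censoring is uniform on (0, censor_time_max].
    """

    n_patients: int = 49
    prop_score_positive: float = 16 / 49
    baseline_hazard: float = 0.002
    hazard_ratio_positive: float = 15.02
    censor_time_max: float = 72.0
    covariate_prevalences: dict[str, float] = field(default_factory=dict)
    covariate_hazard_ratios: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not (0.0 <= self.prop_score_positive <= 1.0):
            raise ValueError("prop_score_positive must be in [0, 1]")
        if self.baseline_hazard <= 0 or self.censor_time_max <= 0:
            raise ValueError("baseline_hazard and censor_time_max must be > 0")
        if self.hazard_ratio_positive <= 0:
            raise ValueError("hazard_ratio_positive must be > 0")
        for f, p in self.covariate_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence of {f!r} outside [0, 1]")


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------

def _gene_names(n_genes: int) -> list[str]:
    names = list(DEFAULT_GENES[:n_genes])
    names += [f"GENE{i + 1}" for i in range(len(names), n_genes)]
    return names


def _place_cpgs(n_cpgs: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """Sorted CpG offsets in [0, length-2] with pairwise gaps >= 2."""
    if 2 * n_cpgs > length:
        raise PackingError(
            f"cannot place {n_cpgs} CpGs in an amplicon of length {length}"
        )
    if n_cpgs == 0:
        return np.empty(0, dtype=int)
    # sample a non-decreasing sequence, then stretch by 2 per step
    slack = length - 1 - 2 * (n_cpgs - 1)  # offsets live in [0, slack-1]
    base = np.sort(rng.integers(0, slack, size=n_cpgs))
    return base + 2 * np.arange(n_cpgs)


def _random_sequence(
    length: int, cpg_positions: np.ndarray, rng: np.random.Generator
) -> str:
    """Random ACGT sequence whose only CG dinucleotides are the declared ones."""
    c_set = set(int(p) for p in cpg_positions)
    g_set = set(int(p) + 1 for p in cpg_positions)
    out = []
    prev_free_c = False
    for i in range(length):
        if i in c_set:
            ch = "C"
        elif i in g_set:
            ch = "G"
        else:
            choices = "ACT" if prev_free_c else "ACGT"
            # also never start a CG ending on a declared C (C..C is fine);
            # a free C directly before a declared C cannot form CG
            ch = choices[rng.integers(0, len(choices))]
        prev_free_c = ch == "C" and i not in c_set
        out.append(ch)
    return "".join(out)


def generate_panel(
    n_genes: int = 13,
    total_cpgs: int = 243,
    amplicon_length: int = 300,
    seed: int = 0,
) -> AmpliconPanel:
    """Generate ``n_genes`` amplicons whose CpG counts sum to ``total_cpgs``.

    CpGs are spread as evenly as possible across amplicons; sequences
    contain no CG dinucleotides beyond the declared positions.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_genes == 0:
        if total_cpgs not in (0,):
            raise ValueError("total_cpgs must be 0 for an empty panel")
        return AmpliconPanel(())
    if total_cpgs < n_genes:
        raise ValueError("need at least one CpG per amplicon")
    if amplicon_length < 30:
        raise ValueError("amplicon_length must be >= 30")

    rng = np.random.default_rng(seed)
    counts = [total_cpgs // n_genes] * n_genes
    for i in range(total_cpgs % n_genes):
        counts[i] += 1
    amplicons = []
    for name, k in zip(_gene_names(n_genes), counts):
        pos = _place_cpgs(k, amplicon_length, rng)
        seq = _random_sequence(amplicon_length, pos, rng)
        amplicons.append(Amplicon(name, seq, tuple(int(p) for p in pos)))
    return AmpliconPanel(tuple(amplicons))


# ---------------------------------------------------------------------------
# methylation profiles
# ---------------------------------------------------------------------------

def informative_cpg_ids(panel: AmpliconPanel, fraction: float) -> tuple[str, ...]:
    """The deterministic informative subset: the first ``ceil(f*n)`` panel CpGs.

    Keeping the subset a pure function of the panel makes class separation
    consistent across samples, which is what the discriminant score needs.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    ids = panel.cpg_ids
    return ids[: math.ceil(fraction * len(ids))]


def simulate_profile(
    panel: AmpliconPanel,
    class_label: str,
    informative_fraction: float = 0.3,
    beta_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int = 0,
    sample_id: str | None = None,
) -> MethylationProfile:
    """Draw per-CpG methylation levels from class-conditional Betas."""
    params = DEFAULT_BETA_PARAMS if beta_params is None else beta_params
    if class_label not in params:
        raise ValueError(f"unknown class label {class_label!r}")
    a_i, b_i = params[class_label]["informative"]
    a_b, b_b = params[class_label]["background"]
    rng = np.random.default_rng(seed)
    informative = set(informative_cpg_ids(panel, informative_fraction))
    levels: dict[str, float] = {}
    for cid in panel.cpg_ids:
        a, b = (a_i, b_i) if cid in informative else (a_b, b_b)
        levels[cid] = float(rng.beta(a, b))
    return MethylationProfile(
        sample_id=sample_id or f"{class_label}_{seed}",
        class_label=class_label,
        levels=levels,
    )


# ---------------------------------------------------------------------------
# bisulfite read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    panel: AmpliconPanel,
    profile: MethylationProfile,
    depth: int = 100,
    conversion_efficiency: float = 1.0,
    error_rate: float = 0.0,
    quality: int = 37,
    seed: int = 0,
) -> list[FastqRecord]:
    """Simulate single-strand bisulfite reads, ``depth`` per amplicon.

    Per read, a CpG cytosine stays 'C' with probability m (its methylation
    level); otherwise — and at every non-CpG cytosine — it converts to 'T'
    with probability ``conversion_efficiency``. Uniform substitution errors
    are applied after conversion.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not (0.0 <= conversion_efficiency <= 1.0):
        raise ValueError("conversion_efficiency must be in [0, 1]")
    if not (0.0 <= error_rate <= 1.0):
        raise ValueError("error_rate must be in [0, 1]")
    panel_ids = set(panel.cpg_ids)
    extra = set(profile.levels) - panel_ids
    if extra:
        raise ValueError(f"profile references CpGs absent from panel: {sorted(extra)}")
    missing = panel_ids - set(profile.levels)
    if missing:
        raise ValueError(f"profile lacks levels for panel CpGs: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    reads: list[FastqRecord] = []
    for amp in panel:
        seq = np.frombuffer(amp.sequence.encode(), dtype=np.uint8)
        L = len(seq)
        mat = np.tile(seq, (depth, 1))
        cpg_pos = np.array(amp.cpg_positions, dtype=int)
        is_c = seq == ord("C")
        non_cpg_c = np.flatnonzero(is_c & ~np.isin(np.arange(L), cpg_pos))

        if depth:
            # CpG cytosines: unmethylated ones convert with prob e
            for p, cid in zip(cpg_pos, amp.cpg_ids):
                m = profile.levels[cid]
                unmeth = rng.random(depth) >= m
                convert = unmeth & (rng.random(depth) < conversion_efficiency)
                mat[convert, p] = ord("T")
            # non-CpG cytosines always eligible for conversion
            if non_cpg_c.size:
                conv = rng.random((depth, non_cpg_c.size)) < conversion_efficiency
                sub = mat[:, non_cpg_c]
                sub[conv] = ord("T")
                mat[:, non_cpg_c] = sub
            # substitution errors after conversion
            if error_rate > 0:
                err = rng.random((depth, L)) < error_rate
                n_err = int(err.sum())
                if n_err:
                    cur = mat[err]
                    shift = rng.integers(1, 4, size=n_err)
                    cur_idx = np.searchsorted(_BASES, cur)
                    mat[err] = _BASES[(cur_idx + shift) % 4]

        qual = tuple([int(quality)] * L)
        for i in range(depth):
            reads.append(
                FastqRecord(f"{amp.gene_name}|{i}", mat[i].tobytes().decode(), qual)
            )
    return reads


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: Default factor prevalences, loosely mirroring a 49-patient oral-cancer
#: cohort; multi-level factors carry per-level probabilities.
DEFAULT_PREVALENCES: dict[str, object] = {
    "sex": 19 / 49,  # P(Male)
    "site": {
        "Tongue": 17 / 49, "Floor of mouth": 1 / 49, "Cheek": 4 / 49,
        "Soft palate": 0.0, "Superior gum/hard palate": 7 / 49,
        "Inferior gum": 19 / 49, "Lip": 1 / 49,
    },
    "grade": {"G1": 20 / 49, "G2": 21 / 49, "G3": 8 / 49},
    "t_stage": 21 / 49,  # P(T3-4)
    "n_positive": 7 / 49,  # P(N+)
    "perineural": 7 / 49,
    "vascular": 3 / 49,
    "margin": {"Clear": 45 / 49, "Close": 3 / 49, "Dysplasia": 1 / 49},
    "opmd": {"No": 42 / 49, "Oral Lichen Planus": 5 / 49, "Leukoplakia": 2 / 49},
    "radiotherapy": 22 / 49,
    "flap": 26 / 49,
}


def _draw_factor(
    factor: str, prevalence: object, n: int, rng: np.random.Generator
) -> np.ndarray:
    levels = FACTOR_LEVELS[factor]
    if isinstance(prevalence, dict):
        probs = np.array([prevalence.get(lv, 0.0) for lv in levels], dtype=float)
        probs = probs / probs.sum()
        return rng.choice(np.array(levels, dtype=object), size=n, p=probs)
    # scalar = probability of the non-reference (second) level
    hit = rng.random(n) < float(prevalence)
    return np.where(hit, levels[1], levels[0]).astype(object)


def simulate_cohort(
    spec: CohortSpec,
    panel: AmpliconPanel | None = None,
    informative_fraction: float = 0.3,
    beta_params: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> tuple[pd.DataFrame, list[MethylationProfile] | None]:
    """Simulate a follow-up cohort; optionally pair each patient with a
    regenerative-area methylation profile (tumor-like if score-positive)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    positive = rng.random(n) < spec.prop_score_positive

    prevalences = dict(DEFAULT_PREVALENCES)
    prevalences.update(spec.covariate_prevalences)
    factors = {f: _draw_factor(f, prevalences[f], n, rng) for f in FACTOR_LEVELS}

    hazard = np.full(n, spec.baseline_hazard)
    hazard[positive] *= spec.hazard_ratio_positive
    for factor, hr in spec.covariate_hazard_ratios.items():
        at_risk = factors[factor] == FACTOR_LEVELS[factor][1]
        hazard[at_risk] *= hr
    event_time = rng.exponential(1.0 / hazard) if n else np.empty(0)
    censor_time = rng.uniform(0.0, spec.censor_time_max, size=n)
    censor_time = np.maximum(censor_time, 1e-9)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    age = np.clip(rng.normal(67.0, 11.5, size=n), 18, 100).round(1)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            **factors,
            "age": age,
            "score_positive": positive,
            "time_months": np.maximum(time, 1e-9),
            "event": event,
        },
        columns=list(COHORT_COLUMNS),
    )
    validate_cohort(df)

    profiles = None
    if panel is not None:
        profiles = []
        seeds = rng.integers(0, 2**31 - 1, size=n)
        for i in range(n):
            cls = "tumor" if positive[i] else "healthy"
            profiles.append(
                simulate_profile(
                    panel,
                    cls,
                    informative_fraction=informative_fraction,
                    beta_params=beta_params,
                    seed=int(seeds[i]),
                    sample_id=df["patient_id"].iloc[i],
                )
            )
    return df, profiles
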