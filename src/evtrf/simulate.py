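"""Seeded generators for references, small-RNA cohorts, and qPCR plates.

The study's raw sequencing data are emulated rather than downloaded: EV
libraries dominated by 30-34 nt 5'-tRNA halves, tissue libraries with a
22 nt miRNA peak, configurable group fold changes on selected tRF
fragments, 1-2 nt indel variants of canonical 5'-tRFs, background RPM
tables standing in for blood-cell EV datasets, and Cq plates under an
amplification-efficiency model.  Every generator is deterministic for a
fixed seed, and a truth table records each fragment's source, class, tRF
type, fold change and indel count so downstream recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .refdb import RNA_CLASSES, ReferenceRecord, ReferenceSet

BASES = np.array(list("ACGT"))

#: Class mixture of reads per compartment profile.  EV libraries are
#: dominated by tRNA halves; tissue shows the usual rRNA/miRNA picture.
DEFAULT_CLASS_MIX = {
    "ev": {"tRNA": 0.72, "rRNA": 0.12, "miRNA": 0.06, "piRNA": 0.05, "snoRNA": 0.05},
    "tissue": {"miRNA": 0.45, "rRNA": 0.33, "tRNA": 0.08, "piRNA": 0.07, "snoRNA": 0.07},
}

#: tRF insert lengths peak at 30-34 nt (mode 32) in EV libraries.
TRF_LENGTHS = (30, 31, 32, 33, 34)
TRF_LENGTH_P = (0.10, 0.20, 0.40, 0.20, 0.10)
#: miRNA lengths 20-24, strongly moded at the canonical 22 nt.
MIRNA_LENGTHS = (20, 21, 22, 23, 24)
MIRNA_LENGTH_P = (0.08, 0.12, 0.60, 0.12, 0.08)

DEFAULT_N_REFS = {"tRNA": 60, "miRNA": 60, "piRNA": 40, "snoRNA": 25, "rRNA": 8}
DEFAULT_N_FRAGMENTS = {"tRNA": 120, "miRNA": 70, "piRNA": 50, "snoRNA": 30, "rRNA": 70}

ILLUMINA_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the study design: 8 preeclampsia (case) vs 6
    normotensive (control) EV libraries, overdispersed negative-binomial
    counts, and a small fraction of tRF fragments emitted as 1-2 nt indel
    variants of their canonical 5'-tRF.
    """

    seed: int
    n_case: int = 8
    n_control: int = 6
    profile: str = "ev"  # "ev" (MLEV/SEV-like) or "tissue"
    compartment: str = "MLEV"
    class_mix: Mapping[str, float] | None = None
    n_refs: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_REFS))
    n_fragments: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_FRAGMENTS)
    )
    de_spec: Sequence[tuple[str, float]] | None = None
    n_de: int = 0
    de_fold: float = 4.0
    de_min_rpm: float = 500.0
    variant_fraction: float = 0.0
    substitution_error_rate: float = 0.0
    library_size: int = 30_000
    dispersion: float = 0.3
    adapter: str = ILLUMINA_SMALL_RNA_ADAPTER
    read_length: int = 50
    lognormal_sigma: float = 1.3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("both groups need at least one sample")
        if self.profile not in DEFAULT_CLASS_MIX:
            raise ValueError(f"unknown profile {self.profile!r}")
        if not 0.0 <= self.variant_fraction < 1.0:
            raise ValueError("variant_fraction must lie in [0, 1)")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("substitution_error_rate must lie in [0, 1)")
        if self.de_spec is not None:
            for _, fold in self.de_spec:
                if fold <= 0:
                    raise ValueError("fold changes must be positive")
        mix = dict(self.class_mix or DEFAULT_CLASS_MIX[self.profile])
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("class mixture proportions must sum to 1")
        self.class_mix = mix

    @property
    def samples(self) -> list[str]:
        return [f"case_{i+1}" for i in range(self.n_case)] + [
            f"control_{i+1}" for i in range(self.n_control)
        ]

    @property
    def groups(self) -> pd.Series:
        g = ["case"] * self.n_case + ["control"] * self.n_control
        return pd.Series(g, index=self.samples, name="group")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def simulate_references(config: SimulationConfig) -> dict[str, ReferenceSet]:
    """Random reference sets with class-appropriate lengths.

    tRNA 72-90 nt (CCA-terminated), miRNA 20-24 (mode 22), piRNA 26-32,
    snoRNA 60-100, rRNA-derived windows 100-200 nt.  Deterministic for a
    fixed seed.
    """
    for cls, n in config.n_refs.items():
        if n <= 0:
            raise ValueError(f"n_refs[{cls!r}] must be positive")
    rng = np.random.default_rng(config.seed)
    sets: dict[str, ReferenceSet] = {}
    amino = ["Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His",
             "Ile", "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp",
             "Tyr", "Val"]
    for cls in RNA_CLASSES:
        n = config.n_refs.get(cls, 0)
        refset = ReferenceSet(cls)
        for i in range(n):
            if cls == "tRNA":
                length = int(rng.integers(72, 91))
                seq = _random_seq(rng, length - 3) + "CCA"
                aa = amino[i % len(amino)]
                anticodon = _random_seq(rng, 3)
                ref_id = f"tRNA-{aa}-{anticodon}-{i // len(amino) + 1}-1"
                meta = {"amino_acid": aa, "anticodon": anticodon}
            else:
                if cls == "miRNA":
                    length = int(rng.choice(MIRNA_LENGTHS, p=MIRNA_LENGTH_P))
                elif cls == "piRNA":
                    length = int(rng.integers(26, 33))
                elif cls == "snoRNA":
                    length = int(rng.integers(60, 101))
                else:  # rRNA-derived window
                    length = int(rng.integers(100, 201))
                seq = _random_seq(rng, length)
                ref_id = f"{cls}-{i+1}"
                meta = {}
            refset.add(ReferenceRecord(ref_id, cls, seq, meta))
        sets[cls] = refset
    return sets


def _levenshtein_small(a: str, b: str) -> int:
    """Plain full-matrix Levenshtein for generator-side truth checks."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _realized_edits(frag: str, source_seq: str, window: int = 2) -> int:
    """Minimal edit distance from ``frag`` to any 5' prefix of its source
    tRNA within ``window`` of the fragment length."""
    best = len(frag)
    for L in range(max(1, len(frag) - window), min(len(source_seq), len(frag) + window) + 1):
        best = min(best, _levenshtein_small(frag, source_seq[:L]))
    return best


def _apply_indels(
    rng: np.random.Generator, seq: str, n_ops: int, protect: int = 3
) -> str:
    """Apply ``n_ops`` random 1-nt indels, never inside the first ``protect``
    nt, so the 5' anchor of the fragment stays intact."""
    s = list(seq)
    for _ in range(n_ops):
        if rng.random() < 0.5 and len(s) > protect + 1:
            pos = int(rng.integers(protect, len(s)))
            del s[pos]
        else:
            pos = int(rng.integers(protect, len(s) + 1))
            s.insert(pos, str(rng.choice(BASES)))
    return "".join(s)


def build_fragment_universe(
    config: SimulationConfig, refs: Mapping[str, ReferenceSet]
) -> pd.DataFrame:
    """Draw the cohort's fragment universe with ground truth.

    Returns a DataFrame indexed by fragment sequence with columns
    ``source_ref``, ``rna_class``, ``trf_type``, ``edit_count``,
    ``weight`` (within-class relative abundance, summing to 1 per class)
    and ``fold_change`` (case/control; 1 for null fragments).

    tRNA fragments are exact 5' prefixes of a random tRNA (30-34 nt); a
    configured fraction instead carries a fixed 1-2 nt indel variant of its
    prefix.  miRNA/piRNA fragments are whole references; snoRNA and rRNA
    fragments are internal windows.  Differentially expressed fragments are
    drawn from tRF fragments whose expected control abundance is at least
    ``de_min_rpm``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows: list[dict] = []
    seen: set[str] = set()
    for cls, n_frag in config.n_fragments.items():
        if n_frag <= 0:
            raise ValueError(f"n_fragments[{cls!r}] must be positive")
        refset = refs[cls]
        ids = refset.ids()
        for _ in range(n_frag):
            for _attempt in range(100):
                ref = refset[ids[int(rng.integers(len(ids)))]]
                trf_type = ""
                edits = 0
                if cls == "tRNA":
                    length = int(rng.choice(TRF_LENGTHS, p=TRF_LENGTH_P))
                    frag = ref.sequence[:length]
                    trf_type = "five_prime"
                    if rng.random() < config.variant_fraction:
                        edits = 1 if rng.random() < 0.6 else 2
                        frag = _apply_indels(rng, frag, edits)
                        # reject degenerate draws whose applied ops reduce
                        # (e.g. an insert/delete pair cancelling inside a
                        # homopolymer run), so the recorded edit count is the
                        # realized distance to the canonical 5'-tRF
                        if _realized_edits(frag, ref.sequence) != edits:
                            continue
                elif cls in ("miRNA", "piRNA"):
                    frag = ref.sequence
                elif cls == "snoRNA":
                    length = int(rng.integers(20, 41))
                    start = int(rng.integers(0, len(ref.sequence) - length + 1))
                    frag = ref.sequence[start : start + length]
                else:  # rRNA
                    length = int(rng.integers(16, 46))
                    start = int(rng.integers(0, len(ref.sequence) - length + 1))
                    frag = ref.sequence[start : start + length]
                if frag not in seen:
                    break
            else:
                continue  # could not find a fresh fragment; skip slot
            seen.add(frag)
            rows.append(
                {
                    "fragment": frag,
                    "source_ref": ref.ref_id,
                    "rna_class": cls,
                    "trf_type": trf_type,
                    "edit_count": edits,
                }
            )
    truth = pd.DataFrame(rows).set_index("fragment")

    # Within-class relative abundances: log-normal, normalised per class.
    weights = np.exp(rng.normal(0.0, config.lognormal_sigma, size=len(truth)))
    truth["weight"] = weights
    truth["weight"] = truth.groupby("rna_class")["weight"].transform(
        lambda w: w / w.sum()
    )
    truth["fold_change"] = 1.0

    if config.de_spec is not None:
        for frag, fold in config.de_spec:
            if frag not in truth.index:
                raise ValueError(f"de_spec references unknown fragment {frag!r}")
            truth.loc[frag, "fold_change"] = float(fold)
    elif config.n_de > 0:
        trf = truth[truth["rna_class"] == "tRNA"]
        eligible = trf.index[1e6 * trf["weight"] >= config.de_min_rpm]
        if len(eligible) < config.n_de:
            raise ValueError(
                f"only {len(eligible)} tRF fragments reach {config.de_min_rpm} RPM; "
                f"cannot place {config.n_de} DE fragments"
            )
        chosen = rng.choice(np.array(eligible), size=config.n_de, replace=False)
        truth.loc[chosen, "fold_change"] = config.de_fold
    return truth


def simulate_counts(
    config: SimulationConfig, truth: pd.DataFrame
) -> pd.DataFrame:
    """Negative-binomial fragment counts per sample.

    The expected count of fragment f in sample s is
    ``library_size * mix[class(f)] * weight_f * fold_f``(case only), with
    gamma-Poisson (NB) noise of the configured dispersion (var = m + a m^2).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    mix = pd.Series(config.class_mix)
    base_mean = (
        config.library_size
        * truth["rna_class"].map(mix).to_numpy(float)
        * truth["weight"].to_numpy(float)
    )
    fold = truth["fold_change"].to_numpy(float)
    counts = {}
    for sample, group in config.groups.items():
        mean = base_mean * (fold if group == "case" else 1.0)
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, mean / shape)
        else:
            lam = mean
        counts[sample] = rng.poisson(lam)
    out = pd.DataFrame(counts, index=truth.index)
    return out


def _mutate_read(rng: np.random.Generator, seq: str, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    s = list(seq)
    for pos in rng.choice(len(s), size=n_err, replace=False):
        alt = [b for b in "ACGT" if b != s[pos]]
        s[pos] = alt[int(rng.integers(3))]
    return "".join(s)


def simulate_cohort(
    config: SimulationConfig,
    refs: Mapping[str, ReferenceSet],
    outdir: str | Path,
) -> tuple[dict[str, Path], pd.DataFrame, pd.DataFrame]:
    """Write per-sample FASTQ files plus truth table and sample sheet.

    Reads are the fragment sequence, optionally substitution-mutated, with
    the 3' adapter appended and random padding out to ``read_length``
    (truncated when over).  Quality strings are constant 'I' (Q40).
    Returns (fastq paths by sample, truth, sample sheet).  Byte-identical
    output for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = build_fragment_universe(config, refs)
    counts = simulate_counts(config, truth)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    paths: dict[str, Path] = {}
    for sample in config.samples:
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            i = 0
            for frag, c in counts[sample].items():
                for _ in range(int(c)):
                    read = frag
                    if config.substitution_error_rate > 0:
                        read = _mutate_read(
                            rng, read, config.substitution_error_rate
                        )
                    read = read + config.adapter
                    if len(read) < config.read_length:
                        read = read + _random_seq(
                            rng, config.read_length - len(read)
                        )
                    read = read[: config.read_length]
                    i += 1
                    fh.write(
                        f"@{sample}:{i}\n{read}\n+\n{'I' * len(read)}\n"
                    )
        paths[sample] = path

    sheet = pd.DataFrame(
        {
            "sample_id": config.samples,
            "group": config.groups.values,
            "compartment": config.compartment,
        }
    )
    return paths, truth, sheet


def simulate_background_rpm(
    truth: pd.DataFrame,
    n_datasets: int = 3,
    seed: int = 0,
    high_fraction: float = 0.15,
    high_rpm: float = 5_000.0,
    low_rpm: float = 10.0,
) -> pd.DataFrame:
    """Synthetic stand-in for blood-cell EV background RPM tables.

    Most fragments are near-absent from the background datasets (around
    ``low_rpm``); a random ``high_fraction`` is abundant (around
    ``high_rpm``), emulating tRFs shared with immune-cell EVs that must be
    screened out during qPCR target selection.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    frags = truth.index
    data = {}
    high = rng.random(len(frags)) < high_fraction
    for d in range(n_datasets):
        base = np.where(high, high_rpm, low_rpm)
        data[f"background_{d+1}"] = base * np.exp(rng.normal(0, 0.5, len(frags)))
    return pd.DataFrame(data, index=frags)


def simulate_qpcr(
    abundance: pd.DataFrame,
    groups: pd.Series | Mapping[str, str],
    efficiency: float | Mapping[str, float] = 2.0,
    noise_sd: float = 0.1,
    intercept: float = 32.0,
    censor_cq: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cq plate under the efficiency model
    ``Cq = intercept - log_E(abundance) + N(0, noise_sd)``.

    ``abundance`` is samples x assays (relative template amounts).
    Non-positive abundance emits ``censor_cq`` (undetectable by
    construction).  Deterministic per seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    groups = pd.Series(groups)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    rows = []
    for assay in abundance.columns:
        E = efficiency[assay] if isinstance(efficiency, Mapping) else efficiency
        if not 1.0 < E <= 2.0:
            raise ValueError(f"efficiency for {assay!r} must lie in (1, 2]")
        for sample in abundance.index:
            amount = float(abundance.loc[sample, assay])
            if amount <= 0:
                cq = censor_cq
            else:
                cq = intercept - math.log(amount, E)
                if noise_sd > 0:
                    cq += rng.normal(0, noise_sd)
            rows.append(
                {
                    "sample_id": sample,
                    "group": groups.get(sample, ""),
                    "assay": assay,
                    "Cq": cq,
                    "efficiency": E,
                }
            )
    return pd.DataFrame(rows)


def simulate_validation_plate(
    fold: float = 1.4,
    n_case: int = 14,
    n_control: int = 12,
    efficiency: float = 2.0,
    noise_sd: float = 0.3,
    loading_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """One target/reference/spike plate with a known case-group fold change.

    Per-sample loading variation multiplies target and endogenous reference
    alike (so the Pfaffl ratio cancels it); the spike-in assay is emitted at
    constant abundance.  Defaults mirror the plasma STB-EV validation
    design (14 preeclampsia vs 12 normotensive, 1.4-fold).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    samples = [f"case_{i+1}" for i in range(n_case)] + [
        f"control_{i+1}" for i in range(n_control)
    ]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples
    )
    loading = np.exp(rng.normal(0, loading_sd, len(samples)))
    target = 100.0 * loading * np.where(groups == "case", fold, 1.0)
    reference = 500.0 * loading
    spike = np.full(len(samples), 1000.0)
    abundance = pd.DataFrame(
        {"target": target, "reference": reference, "spike": spike}, index=samples
    )
    return simulate_qpcr(
        abundance, groups, efficiency=efficiency, noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )
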