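"""Ground-truth simulator of degenerate yeast telomere repeats.

Yeast telomerase adds imperfect, degenerate TG1-3 repeats, so every clone of
a telomere carries a sequence-distinguishable distal region.  The simulator
emulates the processes the divergence assay rests on:

* a repeat grammar emitting (T G^k, k in 1..3) units on the G-rich strand;
* end-replication shortening of 3-4 nt per generation without telomerase;
* rare divergence (recombination-like) events replacing the sequence distal
  to a random breakpoint with freshly sampled repeats, at a configurable
  per-telomere per-generation rate (default 0.003);
* rare abrupt truncation events;
* telomerase re-extension of telomeres that shorten below a threshold,
  which produces the distal-divergence structure of telomerase-positive
  clone sets;
* a technical artifact layer (PCR / cloning / sequencing): with a per-clone
  probability (default 0.04, the scale of the re-cloning controls) the
  distal sequence is replaced from a random breakpoint, plus background
  isolated substitutions and small (<=6 nt, tolerated-class) indels.

Every emitted clone comes with a :class:`TruthRecord`; identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    CloneSequence,
    TelomereSet,
    write_clone_fasta,
    write_sample_sheet,
)

#: fixed non-telomeric proximal anchor shared by all clones of a locus
DEFAULT_ANCHOR = "ACGCTAGCATCAGTACGATCGAACTGCATG"

_BASES = "ACGT"


def rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    """n independent generators spawned from one master seed (stream i is
    SeedSequence(seed).spawn(n)[i]), so artifacts can be regenerated
    independently."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass(frozen=True)
class RepeatGrammar:
    """Degenerate TG1-3 repeat grammar: units T G^k with k in {1,2,3} drawn
    with probabilities (p1, p2, p3)."""

    p1: float = 0.2
    p2: float = 0.5
    p3: float = 0.3

    def __post_init__(self) -> None:
        if abs(self.p1 + self.p2 + self.p3 - 1.0) > 1e-9:
            raise ValueError("unit probabilities must sum to 1")
        if min(self.p1, self.p2, self.p3) < 0:
            raise ValueError("unit probabilities must be non-negative")

    @property
    def probs(self) -> tuple[float, float, float]:
        return (self.p1, self.p2, self.p3)


_UNITS = ("TG", "TGG", "TGGG")


def sample_telomere(grammar: RepeatGrammar, length_nt: int, rng: np.random.Generator) -> str:
    """Concatenated grammar units clipped to exactly ``length_nt`` (G-rich
    strand, proximal end first)."""
    if length_nt < 1:
        raise ValueError("length must be >= 1")
    parts: list[str] = []
    total = 0
    while total < length_nt:
        k = max(8, (length_nt - total) // 2 + 4)
        draws = rng.choice(3, size=k, p=grammar.probs)
        for d in draws:
            parts.append(_UNITS[d])
            total += len(_UNITS[d])
            if total >= length_nt:
                break
    return "".join(parts)[:length_nt]


@dataclass
class SimulationConfig:
    """Study conditions of a simulated clonal population.

    ``initial_length_nt`` is the telomeric-repeat length of the founder
    (the proximal anchor is added on top).  ``shortening`` is drawn per
    lineage per generation uniformly from {3, 4} nt.  The re-extension
    threshold is compared against the repeat-region length.
    """

    seed: int = 0
    telomerase_active: bool = False
    initial_length_nt: int = 300
    generations: int = 30
    clones_per_set: int = 35
    divergence_rate: float = 0.003
    truncation_rate: float = 0.0
    reextension_threshold_nt: int = 160
    mean_extension_nt: float = 120.0
    proximal_anchor: str = DEFAULT_ANCHOR
    grammar: RepeatGrammar = field(default_factory=RepeatGrammar)

    def __post_init__(self) -> None:
        for name in ("divergence_rate", "truncation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.initial_length_nt < 1 or self.generations < 0:
            raise ValueError("lengths and generations must be positive")


@dataclass
class TechnicalErrorModel:
    """Per-clone artifact layer emulating PCR amplification, propagation in
    E. coli and Sanger sequencing of cloned telomeres.

    ``p_artifact`` is the probability of an artifactual divergence event
    (distal replacement from a uniform breakpoint); the substitution and
    small-indel rates generate only tolerated-class changes (isolated point
    mutations and indels of <= max_indel_nt), kept apart so they never merge
    into a divergent-looking lesion.
    """

    p_artifact: float = 0.04
    substitution_rate: float = 1e-3
    indel_rate: float = 2e-4
    max_indel_nt: int = 6

    def __post_init__(self) -> None:
        for name in ("p_artifact", "substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class LineageEvent:
    generation: int
    kind: str  # divergence | truncation | reextension
    breakpoint: int  # retained proximal bases (0-based length), anchor included
    detail: int = 0  # replaced/extension length


@dataclass
class TruthRecord:
    """Ground truth for one emitted clone (coordinates include the anchor;
    positions are 1-based to match the caller's reporting)."""

    clone_id: str
    true_diverged: bool
    true_divergence_point: Optional[int]
    true_truncation: bool
    event_type: str  # in_vivo | technical | none
    final_length_nt: int
    undiverged_prefix_nt: int
    replaced_tail_nt: int
    eroded: bool
    n_divergence_events: int


# ---------------------------------------------------------------------------
# lineage evolution


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def evolve_lineage(
    config: SimulationConfig,
    rng: np.random.Generator,
    founder: Optional[str] = None,
) -> tuple[str, list[LineageEvent], int, bool]:
    """Evolve one telomere lineage for ``config.generations`` generations.

    Returns (final sequence, event log, undiverged prefix length vs the
    founder, eroded flag).  Per generation: end-replication shortening of
    3-4 nt; with probability divergence_rate a divergence event replaces the
    distal sequence beyond a uniform breakpoint with fresh repeats of the
    same length; with probability truncation_rate an abrupt truncation to a
    uniform shorter length; with telomerase active, re-extension by a
    geometric number of fresh repeat nucleotides whenever the repeat region
    drops below the threshold.
    """
    anchor_len = len(config.proximal_anchor)
    if founder is None:
        founder = config.proximal_anchor + sample_telomere(
            config.grammar, config.initial_length_nt, rng
        )
    seq = founder
    prefix = len(seq)
    events: list[LineageEvent] = []
    eroded = False

    for gen in range(1, config.generations + 1):
        # end-replication shortening
        s = int(rng.integers(3, 5))
        new_len = len(seq) - s
        if new_len <= anchor_len:
            new_len, eroded = anchor_len, True
        seq = seq[:new_len]
        prefix = min(prefix, len(seq))

        # divergence (recombination-like) event
        if rng.random() < config.divergence_rate:
            if len(seq) > anchor_len:
                b = int(rng.integers(anchor_len, len(seq)))
                tail = len(seq) - b
                fresh = sample_telomere(config.grammar, tail, rng)
                # fresh repeats may coincidentally reproduce the first bases
                # of the replaced segment; the sequence-level (observable)
                # breakpoint sits past that shared stretch
                b_eff = b + _common_prefix_len(seq[b:], fresh)
                seq = seq[:b] + fresh
                prefix = min(prefix, b_eff)
            else:
                b, tail = anchor_len, 0
            events.append(LineageEvent(gen, "divergence", b, tail))

        # abrupt truncation
        if config.truncation_rate > 0 and rng.random() < config.truncation_rate:
            if len(seq) > anchor_len + 1:
                new_len = int(rng.integers(anchor_len, len(seq)))
                cut = len(seq) - new_len
                seq = seq[:new_len]
                prefix = min(prefix, new_len)
                events.append(LineageEvent(gen, "truncation", new_len, cut))

        # telomerase re-extension of short telomeres
        if config.telomerase_active and (len(seq) - anchor_len) < config.reextension_threshold_nt:
            ext = int(rng.geometric(1.0 / config.mean_extension_nt))
            events.append(LineageEvent(gen, "reextension", len(seq), ext))
            fresh = sample_telomere(config.grammar, ext, rng)
            if prefix == len(seq) and len(founder) > len(seq):
                # extension diverges from the founder lineage past any
                # coincidental agreement with the eroded founder sequence
                prefix = min(
                    len(founder),
                    len(seq) + _common_prefix_len(founder[len(seq):], fresh),
                )
            seq = seq + fresh

    return seq, events, prefix, eroded


# ---------------------------------------------------------------------------
# technical error layer


def _spaced_positions(
    rng: np.random.Generator, length: int, n: int, taken: list[int], min_dist: int
) -> list[int]:
    """Sample up to n positions in [0, length) at least min_dist away from
    every position already in ``taken`` (and from each other)."""
    out: list[int] = []
    if n <= 0 or length <= 0:
        return out
    cand = rng.choice(length, size=min(n * 4 + 8, length), replace=False)
    for p in cand:
        p = int(p)
        if all(abs(p - q) >= min_dist for q in taken) and all(
            abs(p - q) >= min_dist for q in out
        ):
            out.append(p)
            if len(out) == n:
                break
    return out


def apply_technical_errors(
    seq: str,
    prefix: int,
    model: TechnicalErrorModel,
    rng: np.random.Generator,
    anchor_len: int,
    grammar: RepeatGrammar,
) -> tuple[str, int, bool, int]:
    """Pass one clone through the artifact layer.

    Returns (sequence, updated undiverged prefix, artifact_divergence flag,
    pre-noise length).  Background substitutions/indels are tolerated-class
    by construction: isolated (spaced) point changes and indels of
    <= max_indel_nt kept well apart so adjacent lesions cannot merge into a
    divergent event; they alter the final length slightly but never the
    diverged status.
    """
    artifact = False
    if rng.random() < model.p_artifact and len(seq) > anchor_len:
        b = int(rng.integers(anchor_len, len(seq)))
        tail = len(seq) - b
        fresh = sample_telomere(grammar, tail, rng)
        b_eff = b + _common_prefix_len(seq[b:], fresh)
        seq = seq[:b] + fresh
        prefix = min(prefix, b_eff)
        artifact = True
    pre_noise_len = len(seq)

    L = len(seq)
    n_sub = int(rng.binomial(L, model.substitution_rate))
    sub_pos = _spaced_positions(rng, L, n_sub, [], min_dist=3)
    n_indel = int(rng.binomial(L, model.indel_rate))
    indel_pos = _spaced_positions(
        rng, L, n_indel, sub_pos, min_dist=model.max_indel_nt + 3
    )

    chars = list(seq)
    for p in sub_pos:
        alt = [b for b in _BASES if b != chars[p]]
        chars[p] = alt[int(rng.integers(0, 3))]
    for p in sorted(indel_pos, reverse=True):
        size = int(rng.integers(1, model.max_indel_nt + 1))
        if rng.random() < 0.5 and p + size <= len(chars):  # deletion
            del chars[p : p + size]
        else:  # insertion of fresh repeat sequence
            chars[p:p] = list(sample_telomere(grammar, size, rng))
    return "".join(chars), prefix, artifact, pre_noise_len


# ---------------------------------------------------------------------------
# clone-set emission


@dataclass
class CloneSetResult:
    telomere_set: TelomereSet
    sample_sheet: pd.DataFrame
    truth: list[TruthRecord]
    founder: str


def emit_clone_set(
    config: SimulationConfig,
    error_model: Optional[TechnicalErrorModel] = None,
    rng: Optional[np.random.Generator] = None,
    telomere_id: str = "TEL06R",
    strain_id: str = "SIM1",
    genotype: str = "est2",
) -> CloneSetResult:
    """Emit one clonal population: a founder telomere plus ``clones_per_set``
    clones evolved independently from it (shared proximal history, per-clone
    independent events), each passed through the technical error layer."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    anchor_len = len(config.proximal_anchor)
    founder = config.proximal_anchor + sample_telomere(
        config.grammar, config.initial_length_nt, rng
    )
    clones: list[CloneSequence] = []
    truths: list[TruthRecord] = []
    width = len(str(config.clones_per_set))
    for i in range(config.clones_per_set):
        seq, events, prefix, eroded = evolve_lineage(config, rng, founder=founder)
        n_div = sum(1 for e in events if e.kind == "divergence")
        in_vivo = prefix < len(seq)
        artifact = False
        pre_noise_len = len(seq)
        if error_model is not None:
            seq, prefix, artifact, pre_noise_len = apply_technical_errors(
                seq, prefix, error_model, rng, anchor_len, config.grammar
            )
        diverged = in_vivo or artifact
        if in_vivo:
            event_type = "in_vivo"
        elif artifact:
            event_type = "technical"
        else:
            event_type = "none"
        clone_id = f"clone{i + 1:0{width}d}"
        clones.append(
            CloneSequence(
                clone_id=clone_id,
                telomere_id=telomere_id,
                strain_id=strain_id,
                genotype=genotype,
                generations=float(config.generations),
                bases=seq,
            )
        )
        truths.append(
            TruthRecord(
                clone_id=clone_id,
                true_diverged=diverged,
                true_divergence_point=prefix + 1 if diverged else None,
                true_truncation=prefix < 125,
                event_type=event_type,
                final_length_nt=len(seq),
                undiverged_prefix_nt=prefix,
                replaced_tail_nt=pre_noise_len - prefix if diverged else 0,
                eroded=eroded,
                n_divergence_events=n_div,
            )
        )
    ts = TelomereSet(
        telomere_id=telomere_id,
        strain_id=strain_id,
        genotype=genotype,
        generations=float(config.generations),
        clones=clones,
    )
    sheet = pd.DataFrame(
        {
            "clone_id": [c.clone_id for c in clones],
            "telomere_id": telomere_id,
            "strain_id": strain_id,
            "genotype": genotype,
            "generations": float(config.generations),
        }
    )
    return CloneSetResult(telomere_set=ts, sample_sheet=sheet, truth=truths, founder=founder)


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in truth])


def write_clone_set(result: CloneSetResult, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + sample sheet + truth table; byte-identical per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "clones.fasta",
        "sample_sheet": out / "sample_sheet.tsv",
        "truth": out / "truth.tsv",
    }
    write_clone_fasta(result.telomere_set.clones, paths["fasta"])
    write_sample_sheet(result.sample_sheet, paths["sample_sheet"])
    truth_to_frame(result.truth).to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# caller-vs-truth evaluation


def founder_to_reference_map(founder: str, reference: str) -> np.ndarray:
    """Map founder coordinates (0-based, length+1 entries) onto reference
    coordinates via alignment, so truth breakpoints can be compared with
    called divergence points even when the reference carries tolerated
    indels."""
    from .caller import align_sequences

    cols, _, tail = align_sequences(founder, reference)
    mapping = np.zeros(len(founder) + 1, dtype=int)
    f_pos = r_pos = 0
    for f_base, r_base in cols:
        if f_base is not None:
            mapping[f_pos] = r_pos
            f_pos += 1
        if r_base is not None:
            r_pos += 1
    mapping[f_pos:] = r_pos
    return mapping


@dataclass
class DetectionStats:
    n_true_events: int
    n_detected: int
    n_localized: int
    n_called: int
    n_false_positive: int

    @property
    def recall(self) -> float:
        return self.n_localized / self.n_true_events if self.n_true_events else float("nan")

    @property
    def precision(self) -> float:
        return 1.0 - self.n_false_positive / self.n_called if self.n_called else float("nan")


def evaluate_calls(
    calls: Sequence,
    truth: Sequence[TruthRecord],
    founder: str,
    reference_bases: str,
    min_tail_nt: int = 30,
    tolerance_nt: int = 5,
) -> DetectionStats:
    """Compare caller output with simulator ground truth.

    Recall is measured over clones whose planted event replaced at least
    ``min_tail_nt`` of distal sequence and requires the called divergence
    point within ``tolerance_nt`` of the true breakpoint (translated onto
    reference coordinates).  Precision counts any called-diverged clone
    whose truth record is non-diverged as a false positive.
    """
    by_id = {t.clone_id: t for t in truth}
    fmap = founder_to_reference_map(founder, reference_bases)
    n_true = n_det = n_loc = n_called = n_fp = 0
    for call in calls:
        t = by_id[call.clone_id]
        if call.diverged:
            n_called += 1
            if not t.true_diverged:
                n_fp += 1
        if t.true_diverged and t.replaced_tail_nt >= min_tail_nt:
            n_true += 1
            if call.diverged:
                n_det += 1
                true_bp = fmap[min(t.undiverged_prefix_nt, len(founder))]
                if abs(call.undiverged_length_nt - true_bp) <= tolerance_nt:
                    n_loc += 1
    return DetectionStats(
        n_true_events=n_true,
        n_detected=n_det,
        n_localized=n_loc,
        n_called=n_called,
        n_false_positive=n_fp,
    )


# ---------------------------------------------------------------------------
# senescence density fixtures


@dataclass
class SenescenceProfile:
    """Programmed senescence trajectory for one genotype.

    Densities follow a log-linear V: decline at ``pre_slope`` PD/day into a
    trough of ``trough_density`` at ``trough_day``, then recover at
    ``post_slope`` PD/day; gaussian noise of ``noise_sd`` log2 units is
    added per measurement.
    """

    genotype: str
    strain_id: str
    n_replicates: int
    n_days: int
    trough_day: int
    trough_density: float
    pre_slope: float
    post_slope: float
    noise_sd: float = 0.0

    @classmethod
    def from_trough_pd(
        cls,
        genotype: str,
        strain_id: str,
        target_trough_pd: float,
        trough_day: int,
        n_replicates: int,
        n_days: int,
        trough_density: float = 1e4,
        post_slope: float = 2.0,
        noise_sd: float = 0.0,
        dilution_density: float = 2e5,
    ) -> "SenescenceProfile":
        """Choose the pre-trough slope so the cumulative PD at the trough
        equals ``target_trough_pd`` in expectation."""
        b = np.log2(trough_density / dilution_density)
        t = trough_day
        if t < 2:
            raise ValueError("trough_day must be >= 2 to program a trough PD")
        pre_slope = (target_trough_pd - t * b) / (t * (t - 1) / 2)
        if pre_slope <= 0:
            raise ValueError("target trough PD unreachable with this trough density")
        return cls(
            genotype=genotype,
            strain_id=strain_id,
            n_replicates=n_replicates,
            n_days=n_days,
            trough_day=trough_day,
            trough_density=trough_density,
            pre_slope=pre_slope,
            post_slope=post_slope,
            noise_sd=noise_sd,
        )

    def density(self, day: int) -> float:
        if day <= self.trough_day:
            return self.trough_density * 2.0 ** (self.pre_slope * (self.trough_day - day))
        return self.trough_density * 2.0 ** (self.post_slope * (day - self.trough_day))


def emit_density_fixture(
    profiles: Sequence[SenescenceProfile], rng: np.random.Generator
) -> pd.DataFrame:
    """Daily density tables whose programmed troughs are recoverable by
    curve building; deterministic per generator state."""
    rows = []
    for prof in profiles:
        for rep in range(1, prof.n_replicates + 1):
            for day in range(1, prof.n_days + 1):
                noise = rng.normal(0.0, prof.noise_sd) if prof.noise_sd > 0 else 0.0
                rows.append(
                    {
                        "strain_id": prof.strain_id,
                        "genotype": prof.genotype,
                        "replicate_id": f"{prof.strain_id}_r{rep}",
                        "day": day,
                        "density": prof.density(day) * 2.0**noise,
                    }
                )
    return pd.DataFrame(rows)
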