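"""Synthetic data with known truth for every pipeline stage.

Generates (a) gene/intron annotations, (b) stranded paired-end-style
aligned reads over those introns with controlled true retention levels,
(c) four-condition inclusion tables whose combined-perturbation effect is
a noisy weighted mean of the two single-perturbation effects, and (d)
noisy anisotropy titrations — each with a truth table, each byte-
deterministic per seed.

Read counts follow the mixture the retention statistic assumes: with true
retention psi and target informative depth d, spliced junction reads are
drawn as s ~ Poisson(d·(1−psi)/(1+psi)) and boundary-crossing unspliced
reads as u ~ Poisson(d·2psi/(1+psi)), so that E[u]/(E[u] + 2·E[s]) = psi
and E[u + s] = d. Nuisance intronic and non-matching split reads are added
at configured fractions. Reads are emitted pre-aligned (SAM, coordinate
sorted) — alignment itself is out of scope — and are placed so that each
read overlaps only the intron it was generated for, which makes the truth
table an exact oracle for the classifier.

The default study design mirrors a two-factor perturbation experiment:
four conditions (control, knockout A, knockdown B, combined) with three
replicates each and 50 nt reads from a dUTP-type stranded library.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .alignments import StrandProtocol
from .annotation import GeneModel, Intron, derive_introns
from .binding import anisotropy_model

__all__ = [
    "SimulationConfig",
    "simulate_annotation",
    "simulate_ir_truth",
    "simulate_reads",
    "simulate_inclusion_tables",
    "simulate_binding",
    "echo_config",
]

logger = logging.getLogger(__name__)

# rng stream tags, one per stage, so stages stay independently reproducible
_STREAM_ANNOTATION = 1
_STREAM_READS = 2
_STREAM_TABLES = 3
_STREAM_BINDING = 4
_STREAM_IR_TRUTH = 5


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines every output."""

    seed: int = 0

    # annotation geometry (bases)
    n_genes: int = 50
    introns_per_gene: int = 3
    exon_length_range: tuple[int, int] = (80, 300)
    intron_length_range: tuple[int, int] = (100, 1500)
    intergenic_gap: int = 1000
    chrom: str = "simchr1"
    read_length: int = 50

    # study design: condition -> replicate count
    conditions: dict = field(
        default_factory=lambda: {"WT": 3, "KO": 3, "KD": 3, "KOKD": 3}
    )
    condition_wt: str = "WT"
    condition_a: str = "KO"
    condition_b: str = "KD"
    condition_ab: str = "KOKD"

    # true retention structure
    ir_baseline_range: tuple[float, float] = (0.02, 0.30)
    ir_affected_fraction: float = 0.3
    ir_shift_a: float = 0.10
    ir_shift_b: float = 0.04
    depth: float = 80.0  # expected informative (unspliced + spliced) reads per intron
    frac_intronic: float = 0.05
    frac_alt: float = 0.05
    protocol: str = "second"

    # inclusion tables
    n_events: int = 2000
    as_type_probs: dict = field(
        default_factory=lambda: {"SE": 0.45, "RI": 0.25, "A3SS": 0.12, "MXE": 0.10, "A5SS": 0.08}
    )
    mixture_weight: float = 0.6
    baseline_psi_range: tuple[float, float] = (0.15, 0.85)
    effect_primary_mean: float = 0.12
    effect_primary_sd: float = 0.08
    effect_background_sd: float = 0.02
    affected_event_fraction: float = 0.5
    event_noise_sd: float = 0.02
    replicate_noise_sd: float = 0.05
    read_count_mean_range: tuple[float, float] = (20.0, 300.0)
    read_count_dispersion: float = 10.0
    flank_exon_range: tuple[int, int] = (60, 600)

    # binding titration (molar / dimensionless)
    binding_kd: float = 1e-6
    binding_a_free: float = 0.06
    binding_a_bound: float = 0.20
    binding_rna_total: float = 20e-9
    binding_protein_concs: tuple = (
        0.0, 5e-8, 1e-7, 2e-7, 4e-7, 8e-7, 1.2e-6, 2e-6, 3e-6, 5e-6, 7.5e-6, 1e-5
    )
    binding_noise_frac: float = 0.01  # multiplicative Gaussian noise on A_T

    def validate(self) -> "SimulationConfig":
        for name in ("ir_affected_fraction", "frac_intronic", "frac_alt", "mixture_weight",
                     "affected_event_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("exon_length_range", "intron_length_range"):
            lo, hi = getattr(self, name)
            if not 1 <= lo <= hi:
                raise ValueError(f"infeasible {name}: ({lo}, {hi})")
        if self.exon_length_range[0] < self.read_length + 20:
            raise ValueError(
                "exon_length_range minimum must exceed read_length + 20 so reads for one "
                "intron cannot reach a neighbouring intron"
            )
        if self.intron_length_range[0] < 50:
            raise ValueError("intron_length_range minimum must be >= 50")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if abs(sum(self.as_type_probs.values()) - 1.0) > 1e-9:
            raise ValueError("as_type_probs must sum to 1")
        if self.condition_wt not in self.conditions:
            raise ValueError("conditions must include the control condition")
        return self

    def require_full_design(self) -> "SimulationConfig":
        """The mixture stages need all four conditions of the design."""
        needed = (self.condition_wt, self.condition_a, self.condition_b, self.condition_ab)
        missing = [c for c in needed if c not in self.conditions]
        if missing:
            raise ValueError(f"conditions must include {missing} for the mixture design")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("exon_length_range", "intron_length_range", "baseline_psi_range",
                    "ir_baseline_range", "read_count_mean_range", "flank_exon_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "binding_protein_concs" in data:
            data["binding_protein_concs"] = tuple(data["binding_protein_concs"])
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**data).validate()

    @property
    def strand_protocol(self) -> StrandProtocol:
        return StrandProtocol.from_string(self.protocol)


def echo_config(config: SimulationConfig, path: str | Path) -> None:
    """Write the fully resolved config as YAML (the run's provenance echo)."""
    data = asdict(config)
    for key, value in data.items():
        if isinstance(value, tuple):
            data[key] = list(value)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def _rng(config: SimulationConfig, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, *extra])


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig) -> tuple[list[GeneModel], list[Intron]]:
    """Genes with alternating exons and introns on both strands.

    Genes are laid out sequentially (never overlapping) along one
    chromosome, alternating strands, with intergenic gaps. The emitted
    intron list equals ``derive_introns`` on the emitted genes.
    """
    config.validate()
    rng = _rng(config, _STREAM_ANNOTATION)
    exon_lo, exon_hi = config.exon_length_range
    intron_lo, intron_hi = config.intron_length_range
    genes: list[GeneModel] = []
    cursor = 1000
    for i in range(config.n_genes):
        n_exons = config.introns_per_gene + 1
        exon_lens = rng.integers(exon_lo, exon_hi + 1, size=n_exons)
        intron_lens = rng.integers(intron_lo, intron_hi + 1, size=max(n_exons - 1, 0))
        exons = []
        pos = cursor
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        genes.append(
            GeneModel(
                gene_id=f"gene{i:04d}",
                chrom=config.chrom,
                strand="+" if i % 2 == 0 else "-",
                exons=tuple(exons),
            )
        )
        cursor = pos + config.intergenic_gap
    return genes, derive_introns(genes)


def simulate_ir_truth(config: SimulationConfig, introns: Sequence[Intron]) -> pd.DataFrame:
    """True per-intron, per-condition retention levels.

    Baseline retention is uniform on ``ir_baseline_range``; a random
    subset (``ir_affected_fraction``) of introns responds to the
    perturbations, with the combined condition shifted by the mixture
    (1−w)·shift_a + w·shift_b. Values are clipped to [0, 1].
    """
    rng = _rng(config, _STREAM_IR_TRUTH)
    n = len(introns)
    baseline = rng.uniform(*config.ir_baseline_range, size=n)
    affected = rng.random(n) < config.ir_affected_fraction
    w = config.mixture_weight
    shifts = {
        config.condition_wt: 0.0,
        config.condition_a: config.ir_shift_a,
        config.condition_b: config.ir_shift_b,
        config.condition_ab: (1 - w) * config.ir_shift_a + w * config.ir_shift_b,
    }
    data = {}
    for cond in config.conditions:
        shift = shifts.get(cond, 0.0)
        data[cond] = np.clip(baseline + np.where(affected, shift, 0.0), 0.0, 1.0)
    truth = pd.DataFrame(data, index=pd.Index([i.intron_id for i in introns], name="intron_id"))
    return truth


# ---------------------------------------------------------------------------
# reads


def _emit_spliced(rng, intron: Intron, read_length: int) -> tuple[tuple[int, int], ...]:
    left = int(rng.integers(3, read_length - 3 + 1))  # both blocks >= 3 bases
    right = read_length - left
    return ((intron.start - left, intron.start), (intron.end, intron.end + right))


def _emit_unspliced(rng, intron: Intron, read_length: int) -> tuple[tuple[int, int], ...]:
    if rng.integers(0, 2) == 0:  # cross the intron start
        offset = int(rng.integers(1, read_length - 3 + 1))  # bases upstream of the boundary
        start = intron.start - offset
    else:  # cross the intron end
        inside = int(rng.integers(3, read_length - 3 + 1))  # overlap inside the intron
        start = intron.end - inside
    return ((start, start + read_length),)


def _emit_intronic(rng, intron: Intron, read_length: int) -> tuple[tuple[int, int], ...]:
    start = int(rng.integers(intron.start, intron.end - read_length + 1))
    return ((start, start + read_length),)


def _emit_alt(rng, intron: Intron, read_length: int) -> tuple[tuple[int, int], ...]:
    # split read whose gap starts inside the intron: overlaps it, no exact match
    d = int(rng.integers(10, min(30, intron.length - 10) + 1))
    left = int(rng.integers(3, read_length - 3 + 1))
    right = read_length - left
    gap_start = intron.start + d
    return ((gap_start - left, gap_start), (intron.end, intron.end + right))


def _mate_and_strand(rng, gene_strand: str, protocol: StrandProtocol) -> tuple[str, str]:
    """Pick a mate and aligned strand so the read reports on gene_strand."""
    mate = "first" if rng.integers(0, 2) == 0 else "second"
    if protocol is StrandProtocol.UNSTRANDED:
        aligned = "+" if rng.integers(0, 2) == 0 else "-"
        return mate, aligned
    reporting = "second" if protocol is StrandProtocol.SECOND_MATE else "first"
    if mate == reporting:
        return mate, gene_strand
    return mate, "-" if gene_strand == "+" else "+"


def simulate_reads(
    config: SimulationConfig,
    introns: Sequence[Intron],
    outdir: str | Path,
    ir_truth: Optional[pd.DataFrame] = None,
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Per-sample SAM files plus an exact truth table of class counts.

    Returns ``(sam_paths, truth)`` where ``truth`` has one row per
    (intron, sample) with the generating retention level and the realised
    counts of each read class. Reads are placed so they overlap exactly
    one intron; feeding the SAM back through the quantifier reproduces the
    truth counts identically.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if ir_truth is None:
        ir_truth = simulate_ir_truth(config, introns)
    read_length = config.read_length
    protocol = config.strand_protocol

    chrom_len = max(i.end for i in introns) + 10 * read_length + config.intergenic_gap
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": config.chrom, "LN": int(chrom_len)}]}
    )

    short_introns = [i.intron_id for i in introns if i.length < read_length]
    if short_introns and config.frac_intronic > 0:
        logger.warning(
            "simulate_reads: %d introns shorter than the read length; their intronic "
            "read fraction is forced to 0", len(short_introns),
        )

    emitters = {
        "n_spliced": _emit_spliced,
        "n_unspliced": _emit_unspliced,
        "n_intronic": _emit_intronic,
        "n_alt": _emit_alt,
    }

    sam_paths: dict[str, Path] = {}
    truth_rows: list[dict] = []
    sample_index = 0
    for condition, n_reps in config.conditions.items():
        for rep in range(1, n_reps + 1):
            sample_id = f"{condition}_rep{rep}"
            rng = _rng(config, _STREAM_READS, sample_index)
            sample_index += 1
            records: list[tuple[int, str, int, tuple[tuple[int, int], ...], str, str]] = []
            for intron in introns:
                psi = float(ir_truth.loc[intron.intron_id, condition])
                lam_s = config.depth * (1 - psi) / (1 + psi)
                lam_u = config.depth * 2 * psi / (1 + psi)
                counts = {
                    "n_unspliced": int(rng.poisson(lam_u)),
                    "n_intronic": (
                        int(rng.poisson(config.depth * config.frac_intronic))
                        if intron.length >= read_length else 0
                    ),
                    "n_spliced": int(rng.poisson(lam_s)),
                    "n_alt": (
                        int(rng.poisson(config.depth * config.frac_alt))
                        if intron.length >= 40 else 0
                    ),
                }
                for cls_name in ("n_unspliced", "n_intronic", "n_spliced", "n_alt"):
                    emit = emitters[cls_name]
                    for k in range(counts[cls_name]):
                        blocks = emit(rng, intron, read_length)
                        mate, aligned = _mate_and_strand(rng, intron.strand, protocol)
                        name = f"{sample_id}:{intron.intron_id}:{cls_name[2:]}:{k}"
                        records.append((blocks[0][0], name, sample_index, blocks, mate, aligned))
                truth_rows.append(
                    {"intron_id": intron.intron_id, "sample_id": sample_id,
                     "condition": condition, "replicate": f"rep{rep}", "psi": psi, **counts}
                )
            records.sort(key=lambda r: (r[0], r[1]))
            path = outdir / f"{sample_id}.sam"
            with pysam.AlignmentFile(str(path), "w", header=header) as out:
                for _, name, _, blocks, mate, aligned in records:
                    out.write(_to_segment(header, config.chrom, name, blocks, mate, aligned))
            sam_paths[sample_id] = path
    truth = pd.DataFrame(truth_rows)
    return sam_paths, truth


def _to_segment(header, chrom, name, blocks, mate, aligned) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.reference_id = 0
    seg.reference_start = blocks[0][0]
    seg.mapping_quality = 60
    cigar = []
    for idx, (s, e) in enumerate(blocks):
        if idx > 0:
            cigar.append((3, s - blocks[idx - 1][1]))  # N gap
        cigar.append((0, e - s))  # M
    seg.cigartuples = cigar
    qlen = sum(e - s for s, e in blocks)
    seg.query_sequence = "A" * qlen
    flag = 0x1 | (0x40 if mate == "first" else 0x80)
    if aligned == "-":
        flag |= 0x10
    seg.flag = flag
    return seg


# ---------------------------------------------------------------------------
# inclusion tables


def simulate_inclusion_tables(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Four-condition inclusion tables with a known mixture weight.

    Condition A's effect is enriched among retained-intron events and
    condition B's among alternative-3'SS events (the remaining events get
    small background effects); the combined condition's event-level effect
    is (1−w)·effect_a + w·effect_b plus event noise. Replicate PSIs add
    Gaussian noise and are clipped to [0, 1]; read counts are negative
    binomial around a per-event mean. Returns (long inclusion table,
    per-event truth table).
    """
    config.validate().require_full_design()
    rng = _rng(config, _STREAM_TABLES)
    n = config.n_events
    types = list(config.as_type_probs)
    probs = np.array([config.as_type_probs[t] for t in types])
    as_type = rng.choice(types, size=n, p=probs)
    baseline = rng.uniform(*config.baseline_psi_range, size=n)

    def effects(target_type: str) -> np.ndarray:
        eff = rng.normal(0.0, config.effect_background_sd, size=n)
        hit = (as_type == target_type) & (rng.random(n) < config.affected_event_fraction)
        eff[hit] = rng.normal(config.effect_primary_mean, config.effect_primary_sd, int(hit.sum()))
        return eff

    effect_a = effects("RI")
    effect_b = effects("A3SS")
    w = config.mixture_weight
    effect_ab = (1 - w) * effect_a + w * effect_b + rng.normal(0.0, config.event_noise_sd, n)

    lo, hi = config.read_count_mean_range
    count_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    flank_up = rng.integers(*config.flank_exon_range, size=n)
    flank_down = rng.integers(*config.flank_exon_range, size=n)

    event_ids = np.array([f"{t}_{i:06d}" for i, t in enumerate(as_type)])
    cond_effects = {
        config.condition_wt: np.zeros(n),
        config.condition_a: effect_a,
        config.condition_b: effect_b,
        config.condition_ab: effect_ab,
    }

    rows = []
    disp = config.read_count_dispersion
    for cond, n_reps in config.conditions.items():
        mean_psi = baseline + cond_effects.get(cond, np.zeros(n))
        for rep in range(1, n_reps + 1):
            psi = np.clip(mean_psi + rng.normal(0.0, config.replicate_noise_sd, n), 0.0, 1.0)
            counts = rng.negative_binomial(disp, disp / (disp + count_mean), size=n)
            rows.append(
                pd.DataFrame(
                    {
                        "event_id": event_ids,
                        "as_type": as_type,
                        "condition": cond,
                        "replicate": f"rep{rep}",
                        "inclusion_level": psi,
                        "read_count": counts,
                        "flank_exon_lengths": np.where(
                            as_type == "RI",
                            [f"{u},{d}" for u, d in zip(flank_up, flank_down)],
                            None,
                        ),
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(
        {
            "event_id": event_ids,
            "as_type": as_type,
            "baseline_psi": baseline,
            "effect_a": effect_a,
            "effect_b": effect_b,
            "effect_combined": effect_ab,
            "mixture_weight": w,
            "read_count_mean": count_mean,
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# binding


def simulate_binding(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Noisy anisotropy titration from the quadratic isotherm.

    Multiplicative Gaussian noise (``binding_noise_frac``) is applied to
    the model anisotropy at each configured protein concentration.
    """
    config.validate()
    rng = _rng(config, _STREAM_BINDING)
    p = np.asarray(config.binding_protein_concs, dtype=float)
    clean = anisotropy_model(
        p, config.binding_rna_total, config.binding_kd,
        config.binding_a_free, config.binding_a_bound,
    )
    noisy = clean * (1.0 + rng.normal(0.0, config.binding_noise_frac, size=p.size))
    table = pd.DataFrame({"protein_total_M": p, "anisotropy": noisy})
    truth = {
        "kd": config.binding_kd,
        "a_free": config.binding_a_free,
        "a_bound": config.binding_a_bound,
        "rna_total": config.binding_rna_total,
        "noise_frac": config.binding_noise_frac,
    }
    return table, truth
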