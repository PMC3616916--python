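"""Seeded generators for every input the audit pipeline consumes.

Each generator is a pure function of a :class:`SimConfig` (including its
seed) and returns both the simulated input and a :class:`TruthBundle`
recording the planted ground truth, so every downstream stage can be tested
without any external download. Default parameter values are the conditions
of a normalized whole-organism Sanger EST survey: ~14k unique transcripts,
group-specific ORF length and GC content, ~12% read redundancy, a 12-
condition array with nine probes per gene and ~11.7k random null probes, a
14-species gene-family matrix, and a conserved single-copy ortholog set
with a ~21% multi-copy fraction whose extra copies are assembly failures.

Shared identifier universe: the EST id list, the duplicate structure and
the homolog labels are derived from dedicated seed streams, so
`gen_est_set`, `gen_homology_table` and `gen_probe_matrix` called with the
same config emit mutually consistent files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import orf as _orf
from .errors import ConfigurationError
from .homology import OUTFMT6_COLUMNS

_STOPS = ("TAA", "TAG", "TGA")
_NT = np.array(list("ACGT"))

# substreams (kept < 2**31; combined with the user seed via SeedSequence)
_S_GROUPS, _S_DUPS, _S_ORDER = 11, 12, 13
_S_SEQ, _S_SUBST = 21, 22
_S_HITS = 31
_S_COPIES = 41
_S_FAMILIES = 51
_S_PROBES = 61


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic inputs (all generators share one config)."""

    seed: int = 0
    # EST set
    n_ests: int = 14310
    orf_length_mean: float = 339.9  # nt, annotated group
    orf_length_sd: float = 120.0
    orf_length_mean_unannotated: float | None = 183.4  # nt; None -> same as annotated
    gc_annotated: float = 0.500
    gc_unannotated: float = 0.452
    frac_no_start: float = 0.04
    redundancy: float = 0.12
    substitution_rate: float = 0.0  # per-site noise on duplicate reads; off by default
    # homology
    true_match_frac: float = 0.29
    reference_completeness: float = 0.662
    decoy_fraction: float = 0.10  # emitted rows deliberately failing one filter
    # copy-number scenario
    n_families: int = 1115
    frac_multicopy: float = 86 / 415
    copy_count_weights: tuple[tuple[int, int], ...] = ((2, 70), (3, 12), (4, 2), (5, 2))
    # family matrix
    n_species: int = 14
    presence_prob: float = 0.15
    # probe matrix
    n_conditions: int = 12
    probes_per_gene: int = 9
    n_random_probes: int = 11657
    effect_shift: float = 4.0  # intensity units added in expressing conditions
    frac_expressed: float = 0.642

    def validate(self) -> None:
        positive = (
            "n_ests", "n_families", "n_species", "n_conditions",
            "probes_per_gene", "n_random_probes",
        )
        for name in positive:
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        fractions = (
            "gc_annotated", "gc_unannotated", "frac_no_start", "redundancy",
            "substitution_rate", "true_match_frac", "reference_completeness",
            "decoy_fraction", "frac_multicopy", "presence_prob", "frac_expressed",
        )
        for name in fractions:
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a fraction in [0, 1]; got {v}")
        if self.orf_length_mean <= 0 or self.orf_length_sd < 0:
            raise ConfigurationError("orf_length_mean must be > 0 and orf_length_sd >= 0")
        if self.redundancy >= 1.0:
            raise ConfigurationError("redundancy must leave at least one unique read")
        for c, w in self.copy_count_weights:
            if c < 2 or w < 0:
                raise ConfigurationError("copy_count_weights entries must be (count>=2, weight>=0)")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        if "copy_count_weights" in data:
            data["copy_count_weights"] = tuple(
                (int(c), int(w)) for c, w in data["copy_count_weights"]
            )
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class TruthBundle:
    """Planted ground truth accompanying a simulated input."""

    orfs: dict | None = None  # est_id -> {start, end, frame, has_start_codon, orf_length_nt}
    duplicate_groups: dict | None = None  # primary est_id -> [duplicate est ids]
    homologs: list | None = None  # est ids with a true homolog in the reference
    detected_homologs: list | None = None  # homologs the (incomplete) reference can see
    multicopy_families: dict | None = None  # family_id -> planted copy count (>1)
    injected_failure_rate: float | None = None
    exclusive_families: list | None = None  # planted exclusive family ids
    expressed_conditions: dict | None = None  # target_id -> [condition ids]
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthBundle":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


@dataclass(frozen=True)
class _Universe:
    ids: tuple[str, ...]  # final est ids, in emission order
    template: np.ndarray  # unique-transcript index per est
    is_duplicate: np.ndarray  # bool per est
    homolog_unique: np.ndarray  # bool per unique transcript
    n_unique: int


def est_universe(config: SimConfig) -> _Universe:
    """Deterministic shared id universe: duplicates, order, homolog labels."""
    config.validate()
    n_dup = int(round(config.redundancy * config.n_ests))
    n_unique = config.n_ests - n_dup
    homolog_unique = _rng(config, _S_GROUPS).random(n_unique) < config.true_match_frac
    templates_dup = _rng(config, _S_DUPS).integers(0, n_unique, size=n_dup)
    template = np.concatenate([np.arange(n_unique), templates_dup])
    is_dup = np.concatenate(
        [np.zeros(n_unique, dtype=bool), np.ones(n_dup, dtype=bool)]
    )
    order = _rng(config, _S_ORDER).permutation(config.n_ests)
    template = template[order]
    is_dup = is_dup[order]
    ids = tuple(f"AAEST{i + 1:06d}" for i in range(config.n_ests))
    return _Universe(
        ids=ids,
        template=template,
        is_duplicate=is_dup,
        homolog_unique=homolog_unique,
        n_unique=n_unique,
    )


# ---------------------------------------------------------------------------
# EST sequences


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_NT, size=n, p=p)


# 11-mer with stop codons at offsets 0, 4 and 8, i.e. in all three frames
# whatever its phase; used to terminate reading-frame runs in the flanks.
_STOP_WALL = "TAAATGAATAG"
# 4-codon anchor creating stop codons in both shifted frames (TAA across
# CTA|AGC, TGA across ACT|GAC) while being stop- and ATG-free in frame.
_ANCHOR = ("CTA", "AGC", "ACT", "GAC")
_MIN_ORF_CODONS = 10


def _random_codons(
    rng: np.random.Generator, n: int, gc: float, forbid_atg: bool
) -> list[str]:
    forbidden = set(_STOPS) | ({"ATG"} if forbid_atg else set())
    out: list[str] = []
    while len(out) < n:
        block = _random_nt(rng, 3 * (n - len(out)), gc).reshape(-1, 3)
        for row in block:
            codon = "".join(row)
            if codon not in forbidden:
                out.append(codon)
    return out


def _orf_codons(
    rng: np.random.Generator, n: int, gc: float, has_start: bool
) -> list[str]:
    """ORF interior: GC-weighted codons with cross-frame stop anchors.

    An anchor block is inserted after every 6 random codons so that no
    shifted reading frame can run stop-free through the ORF and outgrow it.
    """
    codons: list[str] = ["ATG"] if has_start else []
    since = 0
    while len(codons) < n:
        if since >= 6 and n - len(codons) >= len(_ANCHOR):
            codons.extend(_ANCHOR)
            since = 0
        else:
            codons.extend(_random_codons(rng, 1, gc, forbid_atg=not has_start))
            since += 1
    return codons[:n]


def _utr(rng: np.random.Generator, n: int, gc: float) -> str:
    """Untranslated flank: short random chunks separated by all-frame stop walls."""
    parts: list[str] = []
    size = 0
    while size < n:
        chunk = "".join(_random_nt(rng, int(rng.integers(3, 9)), gc))
        parts.append(chunk)
        parts.append(_STOP_WALL)
        size += len(chunk) + len(_STOP_WALL)
    return "".join(parts)[:n]


def _plant_transcript(
    rng: np.random.Generator,
    orf_codons: int,
    gc: float,
    has_start: bool,
    max_attempts: int = 100,
) -> tuple[str, int, int, int]:
    """Sequence whose longest forward-frame stop-free interval is the planted ORF.

    Returns (sequence, start, end, frame). The planted interval is bracketed
    by stop walls (in-frame stops flush against both ends); the anchor/wall
    structure makes any competing interval shorter, and a verification pass
    redraws the rare boundary tie.
    """
    for _ in range(max_attempts):
        orf_seq = "".join(_orf_codons(rng, orf_codons, gc, has_start))
        utr5 = _utr(rng, int(rng.integers(30, 121)), gc)
        utr3 = _utr(rng, int(rng.integers(60, 241)), gc)
        seq = utr5 + _STOP_WALL + orf_seq + _STOP_WALL + utr3
        start = len(utr5) + len(_STOP_WALL)
        end = start + 3 * orf_codons
        frame = start % 3 + 1
        call = _orf.find_orf(_orf.ESTRecord("tmp", seq), _orf.FORWARD_FRAMES)
        if (call.start, call.end, call.frame) == (start, end, frame):
            return seq, start, end, frame
    raise RuntimeError("could not plant a dominant ORF (raise max_attempts)")


@dataclass(frozen=True)
class EstSet:
    records: tuple[_orf.ESTRecord, ...]
    truth: TruthBundle


def gen_est_set(config: SimConfig) -> EstSet:
    """Simulated EST reads with planted ORFs, group GC, and injected redundancy."""
    uni = est_universe(config)
    rng = _rng(config, _S_SEQ)
    rng_subst = _rng(config, _S_SUBST)
    mean_un = (
        config.orf_length_mean
        if config.orf_length_mean_unannotated is None
        else config.orf_length_mean_unannotated
    )
    # per-unique-transcript sequences, generated in unique-index order
    seqs: list[str] = []
    orf_truth_unique: list[dict] = []
    for u in range(uni.n_unique):
        annotated = bool(uni.homolog_unique[u])
        mean = config.orf_length_mean if annotated else mean_un
        gc = config.gc_annotated if annotated else config.gc_unannotated
        orf_nt = max(30.0, rng.normal(mean, config.orf_length_sd))
        n_codons = max(10, int(round(orf_nt / 3)))
        has_start = bool(rng.random() >= config.frac_no_start)
        seq, start, end, frame = _plant_transcript(rng, n_codons, gc, has_start)
        seqs.append(seq)
        orf_truth_unique.append(
            {
                "start": start,
                "end": end,
                "frame": frame,
                "orf_length_nt": end - start,
                "has_start_codon": has_start,
            }
        )
    records: list[_orf.ESTRecord] = []
    orfs: dict[str, dict] = {}
    primary_id: dict[int, str] = {}
    dup_groups: dict[str, list[str]] = {}
    homologs: list[str] = []
    for est_id, u, is_dup in zip(uni.ids, uni.template, uni.is_duplicate):
        u = int(u)
        seq = seqs[u]
        if is_dup and config.substitution_rate > 0:
            arr = np.array(list(seq))
            hit = rng_subst.random(len(arr)) < config.substitution_rate
            arr[hit] = _random_nt(rng_subst, int(hit.sum()), 0.5)
            seq = "".join(arr)
        records.append(_orf.ESTRecord(id=est_id, sequence=seq))
        orfs[est_id] = dict(orf_truth_unique[u])
        if not is_dup:
            primary_id[u] = est_id
        if uni.homolog_unique[u]:
            homologs.append(est_id)
    for est_id, u, is_dup in zip(uni.ids, uni.template, uni.is_duplicate):
        if is_dup:
            dup_groups.setdefault(primary_id[int(u)], []).append(est_id)
    truth = TruthBundle(
        orfs=orfs,
        duplicate_groups=dup_groups,
        homologs=sorted(homologs),
        extras={"n_unique_transcripts": uni.n_unique},
    )
    return EstSet(records=tuple(records), truth=truth)


def write_fasta(records: Iterable[_orf.ESTRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> list[_orf.ESTRecord]:
    return [
        _orf.ESTRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# ---------------------------------------------------------------------------
# Homology hits


@dataclass(frozen=True)
class HitTable:
    hits: pd.DataFrame  # outfmt-6 column order
    truth: TruthBundle


def gen_homology_table(config: SimConfig, dataset_id: str = "reference") -> HitTable:
    """Simulated tabular homology hits against one reference dataset.

    True homolog transcripts are detectable with probability
    ``reference_completeness`` (detection is decided per transcript, so
    duplicate reads of one transcript share their fate); detected reads get
    1+ passing hits. Non-homologs get no passing hit. An extra
    ``decoy_fraction`` of rows deliberately fail exactly one filter
    (e-value just above 1e-5, or aligned length 32) to exercise boundary
    handling downstream.
    """
    uni = est_universe(config)
    rng = _rng(config, _S_HITS)
    detected_unique = uni.homolog_unique & (
        rng.random(uni.n_unique) < config.reference_completeness
    )
    rows: list[dict] = []

    def _passing_row(query: str, subject: str, log10_e: float) -> dict:
        alen = int(rng.integers(33, 201))
        pid = float(np.round(rng.uniform(35, 95), 1))
        e = 10.0 ** log10_e
        qstart = int(rng.integers(1, 101))
        return {
            "query_id": query,
            "subject_id": subject,
            "percent_identity": pid,
            "aligned_length": alen,
            "mismatches": int(round(alen * (1 - pid / 100))),
            "gap_opens": int(rng.integers(0, 3)),
            "q_start": qstart,
            "q_end": qstart + 3 * alen - 1,
            "s_start": 1,
            "s_end": alen,
            "e_value": e,
            "bit_score": float(np.round(-2.0 * log10_e + 30 + rng.uniform(0, 5), 1)),
        }

    homologs: list[str] = []
    detected: list[str] = []
    for est_id, u in zip(uni.ids, uni.template):
        u = int(u)
        if not uni.homolog_unique[u]:
            continue
        homologs.append(est_id)
        if not detected_unique[u]:
            continue
        detected.append(est_id)
        best_log_e = float(rng.uniform(-60, -6))
        rows.append(_passing_row(est_id, f"REF_{u:06d}", best_log_e))
        for _ in range(int(rng.poisson(0.7))):
            rows.append(
                _passing_row(
                    est_id,
                    f"REF_{int(rng.integers(0, uni.n_unique)):06d}",
                    float(rng.uniform(best_log_e, -6)),
                )
            )
    n_decoys = int(round(config.decoy_fraction * len(rows)))
    for d in range(n_decoys):
        query = uni.ids[int(rng.integers(0, len(uni.ids)))]
        row = _passing_row(query, f"DECOY_{d:05d}", float(rng.uniform(-60, -6)))
        if rng.random() < 0.5:
            row["e_value"] = 10.0 ** float(rng.uniform(-4.99, -3.0))  # just above 1e-5
        else:
            row["aligned_length"] = 32  # just below the length floor
        rows.append(row)
    hits = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
    hits = hits.sort_values(
        ["query_id", "e_value", "subject_id"], kind="mergesort", ignore_index=True
    )
    hits["dataset_id"] = dataset_id
    truth = TruthBundle(
        homologs=sorted(homologs),
        detected_homologs=sorted(detected),
        extras={"dataset_id": dataset_id},
    )
    return HitTable(hits=hits, truth=truth)


def write_hits(hits: pd.DataFrame, path) -> None:
    """Write hits as headerless 12-column tabular TSV (outfmt-6 dialect)."""
    hits[OUTFMT6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Copy-number scenario


@dataclass(frozen=True)
class CopyNumberScenario:
    table: pd.DataFrame  # family_id, n_focal_sequences
    truth: TruthBundle


def gen_copy_number_scenario(config: SimConfig) -> CopyNumberScenario:
    """Conserved single-copy families with a planted multi-copy fraction.

    ``frac_multicopy`` of families get a copy count > 1 drawn from
    ``copy_count_weights``; the extra copies are planted assembly failures.
    The truth bundle records the expected value of the failure-rate
    estimator under these conditions, frac_multicopy / E[copies | multi].
    """
    config.validate()
    rng = _rng(config, _S_COPIES)
    fam_ids = [f"ARP{i + 1:05d}" for i in range(config.n_families)]
    multi = rng.random(config.n_families) < config.frac_multicopy
    counts = np.ones(config.n_families, dtype=int)
    values = np.array([c for c, _ in config.copy_count_weights])
    weights = np.array([w for _, w in config.copy_count_weights], dtype=float)
    weights /= weights.sum()
    counts[multi] = rng.choice(values, size=int(multi.sum()), p=weights)
    table = pd.DataFrame({"family_id": fam_ids, "n_focal_sequences": counts})
    mean_copies = float((values * weights).sum())
    truth = TruthBundle(
        multicopy_families={
            fid: int(c) for fid, c, m in zip(fam_ids, counts, multi) if m
        },
        injected_failure_rate=config.frac_multicopy / mean_copies,
    )
    return CopyNumberScenario(table=table, truth=truth)


# ---------------------------------------------------------------------------
# Family presence/absence matrix


@dataclass(frozen=True)
class FamilyMatrix:
    matrix: pd.DataFrame  # bool, index family_id, columns species
    truth: TruthBundle


def gen_family_matrix(
    config: SimConfig,
    focal: Sequence[str] | None = None,
    n_exclusive: int = 0,
) -> FamilyMatrix:
    """Family-by-species presence matrix with optional planted exclusivity.

    Presence is independent Bernoulli(``presence_prob``) per cell; empty
    families are given one random species. With ``focal`` and
    ``n_exclusive`` set, that many random families are made exclusive to
    the focal set (organic exclusives can exist besides; truth lists only
    the planted ones).
    """
    config.validate()
    rng = _rng(config, _S_FAMILIES)
    species = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    present = rng.random((config.n_families, config.n_species)) < config.presence_prob
    empty = ~present.any(axis=1)
    for i in np.nonzero(empty)[0]:
        present[i, int(rng.integers(0, config.n_species))] = True
    planted: list[str] = []
    fam_ids = [f"FAM{i + 1:05d}" for i in range(config.n_families)]
    if n_exclusive:
        if not focal:
            raise ConfigurationError("n_exclusive requires a focal species set")
        unknown = sorted(set(focal) - set(species))
        if unknown:
            raise ConfigurationError(f"focal names unknown to this matrix: {unknown}")
        focal_idx = [species.index(s) for s in focal]
        if n_exclusive > config.n_families:
            raise ConfigurationError("n_exclusive exceeds n_families")
        rows = rng.choice(config.n_families, size=n_exclusive, replace=False)
        for i in rows:
            present[i, :] = False
            hit = rng.random(len(focal_idx)) < 0.5
            if not hit.any():
                hit[int(rng.integers(0, len(focal_idx)))] = True
            present[i, focal_idx] = hit
            planted.append(fam_ids[i])
    matrix = pd.DataFrame(present, index=pd.Index(fam_ids, name="family_id"),
                          columns=species)
    truth = TruthBundle(
        exclusive_families=sorted(planted),
        extras={"focal": list(focal) if focal else None},
    )
    return FamilyMatrix(matrix=matrix, truth=truth)


def write_family_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.astype(int).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Probe intensities


@dataclass(frozen=True)
class ProbeMatrix:
    matrix: pd.DataFrame  # probe_id, target_id, condition_id, intensity
    truth: TruthBundle


def gen_probe_matrix(config: SimConfig) -> ProbeMatrix:
    """Normalized probe intensities with a standard-normal random-probe null.

    Random probes are N(0, 1) in every condition. Each gene target carries
    ``probes_per_gene`` probes whose intensities are N(0, 1) plus
    ``effect_shift`` in the conditions where the gene is expressed.
    Expressed genes (fraction ``frac_expressed``) express in a random
    subset of 2..n_conditions conditions; with ``effect_shift == 0`` no
    gene is truly expressed and the truth set is empty.
    """
    uni = est_universe(config)
    rng = _rng(config, _S_PROBES)
    targets = list(uni.ids)
    n_t = len(targets)
    n_c = config.n_conditions
    conditions = [f"cond{j + 1:02d}" for j in range(n_c)]
    shift = np.zeros((n_t, n_c))
    expressed_conditions: dict[str, list[str]] = {}
    if config.effect_shift != 0:
        expressed = rng.random(n_t) < config.frac_expressed
        for i in np.nonzero(expressed)[0]:
            size = int(rng.integers(2, n_c + 1))
            which = np.sort(rng.choice(n_c, size=size, replace=False))
            shift[i, which] = config.effect_shift
            expressed_conditions[targets[i]] = [conditions[j] for j in which]
    ppg = config.probes_per_gene
    probe_ids = [f"{t}_p{k + 1}" for t in targets for k in range(ppg)]
    # row order: condition-major, then target, then probe
    gene = pd.DataFrame(
        {
            "probe_id": np.tile(np.array(probe_ids, dtype=object), n_c),
            "target_id": np.tile(np.repeat(np.array(targets, dtype=object), ppg), n_c),
            "condition_id": np.repeat(np.array(conditions, dtype=object), n_t * ppg),
            "intensity": rng.standard_normal(n_t * ppg * n_c)
            + np.repeat(shift.T.ravel(), ppg),
        }
    )
    rand_ids = [f"RANDPROBE{i + 1:06d}" for i in range(config.n_random_probes)]
    random = pd.DataFrame(
        {
            "probe_id": np.tile(rand_ids, n_c),
            "target_id": "RANDOM",
            "condition_id": np.repeat(conditions, config.n_random_probes),
            "intensity": rng.standard_normal(config.n_random_probes * n_c),
        }
    )
    matrix = pd.concat([gene, random], ignore_index=True)
    truth = TruthBundle(expressed_conditions=expressed_conditions)
    return ProbeMatrix(matrix=matrix, truth=truth)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
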