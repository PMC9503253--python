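"""Synthetic case/control cohorts with planted ceRNA structure.

Generates a paired case/control plasma-style cohort: log-normal microarray
intensities for lncRNAs and mRNAs, overdispersed (gamma-Poisson, i.e.
negative-binomial-like) sequencing counts for miRNAs, and two candidate
target-interaction databases (lncRNA->miRNA and miRNA->mRNA).

``n_motifs`` ceRNA motifs are planted: a lncRNA and an mRNA share the same
case-vs-control log2 shift while the shared miRNA shifts in the opposite
direction.  Across samples this induces a strong positive Pearson correlation
between the lncRNA and the mRNA and negative correlations of both with the
miRNA, growing toward +/-1 as ``effect_log2fc`` increases relative to the
noise.  Non-motif (decoy) features carry no group effect.  Matched pairs
share a per-pair, per-feature random offset, which is what gives a paired
t-test its power advantage over an unpaired comparison on these data.

All randomness flows from ``CohortConfig.seed``; identical configs produce
byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import ExpressionMatrix
from .targets import TargetDB, EDGE_TYPES

LNC_MIR = EDGE_TYPES[0]
MIR_MRNA = EDGE_TYPES[1]

#: db_name labels used inside each synthetic target database.  True (planted)
#: edges are recorded under both labels so that combine=intersection keeps
#: them; decoys land under a single random label.
DB_LABELS = {
    LNC_MIR: ("synthdb_lm_A", "synthdb_lm_B"),
    MIR_MRNA: ("synthdb_mm_A", "synthdb_mm_B"),
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the simulated cohort.

    Defaults mirror a small plasma profiling study: three matched
    case/control pairs, tens of features per class, a handful of planted
    ceRNA motifs with a 4-fold (log2 FC = 2) group effect.
    """

    n_pairs: int = 3
    n_lncrna: int = 200
    n_mrna: int = 400
    n_mirna: int = 40
    n_motifs: int = 3
    effect_log2fc: float = 2.0
    intensity_sigma: float = 0.4
    pair_sigma: float = 0.3
    count_dispersion: float = 0.2
    db_decoy_rate: float = 0.25
    probes_per_transcript: tuple[int, int] = (1, 5)
    probe_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "n_lncrna", "n_mrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_motifs < 0:
            raise ValidationError("n_motifs must be >= 0")
        if self.n_motifs > min(self.n_lncrna, self.n_mrna, self.n_mirna):
            raise ValidationError(
                "n_motifs must not exceed min(n_lncrna, n_mrna, n_mirna)"
            )
        if not 0.0 <= self.db_decoy_rate <= 1.0:
            raise ValidationError("db_decoy_rate must be in [0, 1]")
        if self.db_decoy_rate == 1.0 and self.n_motifs > 0:
            raise ValidationError(
                "db_decoy_rate=1 is incompatible with planted motifs: their "
                "true DB edges must be present"
            )
        lo, hi = self.probes_per_transcript
        if not (1 <= lo <= hi <= 5):
            raise ValidationError("probes_per_transcript must satisfy 1 <= lo <= hi <= 5")
        for name in ("intensity_sigma", "pair_sigma", "count_dispersion", "probe_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.effect_log2fc < 0:
            raise ValidationError("effect_log2fc must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of a synthetic cohort.

    ``triples`` are the planted (lncRNA, miRNA, mRNA) motifs;
    ``de_direction`` maps every feature to its true group-shift direction
    (``up``/``down`` for motif members, ``none`` otherwise); ``db_edges``
    lists every DB edge with its type and a ``true``/``decoy`` flag.
    """

    triples: list[tuple[str, str, str]]
    de_direction: dict[str, str]
    db_edges: pd.DataFrame  # columns: edge_type, source_id, target_id, status

    def to_dict(self) -> dict:
        return {
            "triples": [list(t) for t in self.triples],
            "de_direction": self.de_direction,
            "db_edges": self.db_edges.to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthTable":
        return cls(
            triples=[tuple(t) for t in d["triples"]],
            de_direction=dict(d["de_direction"]),
            db_edges=pd.DataFrame(
                d["db_edges"], columns=["edge_type", "source_id", "target_id", "status"]
            ),
        )


@dataclass
class SyntheticCohort:
    """Everything generate_cohort produces, bundled."""

    lncrna: ExpressionMatrix
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    lnc_mir_db: TargetDB
    mir_mrna_db: TargetDB
    truth: TruthTable
    samples: pd.DataFrame
    config: CohortConfig


def _sample_sheet(n_pairs: int) -> pd.DataFrame:
    rows = []
    for i in range(1, n_pairs + 1):
        pair = f"P{i:02d}"
        rows.append((f"case_{pair}", "case", pair))
        rows.append((f"ctrl_{pair}", "control", pair))
    return pd.DataFrame(rows, columns=["sample_id", "group", "pair_id"])


def _intensity_block(
    rng: np.random.Generator,
    ids: list[str],
    shift: np.ndarray,
    pair_off: np.ndarray,
    is_case: np.ndarray,
    pair_index: np.ndarray,
    cfg: CohortConfig,
    columns: list[str],
) -> pd.DataFrame:
    n_feat, n_samp = len(ids), len(is_case)
    # Baselines span the array's log2 dynamic range; shifted (planted)
    # features are placed so both group means stay inside it, since a probe
    # saturating the range would be compressed by quantile normalization.
    lo = 6.0 + np.maximum(-shift, 0.0)
    hi = np.maximum(12.0 - np.maximum(shift, 0.0), lo + 0.5)
    base = rng.uniform(lo, hi)
    noise = rng.normal(0.0, cfg.intensity_sigma, size=(n_feat, n_samp))
    log2v = (
        base[:, None]
        + pair_off[:, pair_index]
        + np.outer(shift, is_case.astype(float))
        + noise
    )
    return pd.DataFrame(2.0 ** log2v, index=ids, columns=columns)


def _count_block(
    rng: np.random.Generator,
    ids: list[str],
    shift: np.ndarray,
    pair_off: np.ndarray,
    is_case: np.ndarray,
    pair_index: np.ndarray,
    cfg: CohortConfig,
    columns: list[str],
) -> pd.DataFrame:
    n_feat, n_samp = len(ids), len(is_case)
    # Mean counts ~16..1024; planted miRNAs stay inside the detectable range
    # in both groups so the shifted group is not all near-zero counts.
    lo = 4.0 + np.maximum(-shift, 0.0)
    hi = np.maximum(10.0 - np.maximum(shift, 0.0), lo + 0.5)
    base = 2.0 ** rng.uniform(lo, hi)
    mean = base[:, None] * 2.0 ** (
        pair_off[:, pair_index] + np.outer(shift, is_case.astype(float))
    )
    if cfg.count_dispersion > 0:
        shape = 1.0 / cfg.count_dispersion
        lam = rng.gamma(shape, mean / shape)  # gamma-Poisson: var = mu + disp*mu^2
    else:
        lam = mean
    counts = rng.poisson(lam)
    return pd.DataFrame(counts.astype(np.int64), index=ids, columns=columns)


def _decoy_edges(
    rng: np.random.Generator,
    sources: list[str],
    targets: list[str],
    true_edges: set[tuple[str, str]],
    rate: float,
) -> list[tuple[str, str]]:
    pool = [
        (s, t) for s in sources for t in targets if (s, t) not in true_edges
    ]
    # rate is the decoy fraction of the final DB: decoys/(decoys+true).
    # With no planted edges the target DB size falls back to one decoy per
    # source feature, scaled by the rate.
    if rate <= 0.0:
        n_decoy = 0
    elif rate >= 1.0:
        n_decoy = len(pool)
    elif true_edges:
        n_decoy = int(round(rate / (1.0 - rate) * len(true_edges)))
    else:
        n_decoy = int(round(rate * len(sources)))
    n_decoy = min(n_decoy, len(pool))
    if n_decoy == 0:
        return []
    idx = rng.choice(len(pool), size=n_decoy, replace=False)
    return [pool[i] for i in idx]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    Returns the three expression matrices (lncRNA/mRNA intensities, miRNA
    counts), the two target databases, the truth table and the sample sheet,
    bundled in a :class:`SyntheticCohort`.  Deterministic given the config.
    """
    rng = np.random.default_rng(config.seed)
    samples = _sample_sheet(config.n_pairs)
    sample_ids = samples["sample_id"].tolist()
    is_case = (samples["group"] == "case").to_numpy()
    pair_index = samples["pair_id"].factorize()[0]

    lnc_ids = [f"LNC{i:04d}" for i in range(1, config.n_lncrna + 1)]
    mrna_ids = [f"GENE{i:04d}" for i in range(1, config.n_mrna + 1)]
    mir_ids = [f"syn-miR-{i:03d}" for i in range(1, config.n_mirna + 1)]

    # Motif members are drawn without replacement from each class.
    motif_lnc = list(rng.choice(lnc_ids, size=config.n_motifs, replace=False))
    motif_mir = list(rng.choice(mir_ids, size=config.n_motifs, replace=False))
    motif_mrna = list(rng.choice(mrna_ids, size=config.n_motifs, replace=False))
    motif_sign = rng.choice([-1.0, 1.0], size=config.n_motifs)

    def shifts(ids: list[str], members: list[str], signs: np.ndarray) -> np.ndarray:
        s = np.zeros(len(ids))
        pos = {f: i for i, f in enumerate(ids)}
        for f, sg in zip(members, signs):
            s[pos[f]] = sg * config.effect_log2fc
        return s

    lnc_shift = shifts(lnc_ids, motif_lnc, motif_sign)
    mrna_shift = shifts(mrna_ids, motif_mrna, motif_sign)
    mir_shift = shifts(mir_ids, motif_mir, -motif_sign)  # miRNA moves opposite

    # Subject-level (per-pair) offsets.  Non-motif features vary
    # independently; the three members of a planted motif are mechanistically
    # coupled and share their pair-level variation (sign-flipped for the
    # miRNA), so the planted correlations do not stop at the group shift.
    lnc_pair = rng.normal(0.0, config.pair_sigma, size=(len(lnc_ids), config.n_pairs))
    mrna_pair = rng.normal(0.0, config.pair_sigma, size=(len(mrna_ids), config.n_pairs))
    mir_pair = rng.normal(0.0, config.pair_sigma, size=(len(mir_ids), config.n_pairs))
    motif_pair = rng.normal(0.0, config.pair_sigma, size=(config.n_motifs, config.n_pairs))
    lnc_pos = {f: i for i, f in enumerate(lnc_ids)}
    mrna_pos = {f: i for i, f in enumerate(mrna_ids)}
    mir_pos = {f: i for i, f in enumerate(mir_ids)}
    for k, (l, m, g) in enumerate(zip(motif_lnc, motif_mir, motif_mrna)):
        lnc_pair[lnc_pos[l]] = motif_pair[k]
        mrna_pair[mrna_pos[g]] = motif_pair[k]
        mir_pair[mir_pos[m]] = -motif_pair[k]

    lnc = ExpressionMatrix(
        _intensity_block(rng, lnc_ids, lnc_shift, lnc_pair, is_case, pair_index, config, sample_ids),
        feature_class="lncRNA",
        kind="intensity",
    )
    mrna = ExpressionMatrix(
        _intensity_block(rng, mrna_ids, mrna_shift, mrna_pair, is_case, pair_index, config, sample_ids),
        feature_class="mRNA",
        kind="intensity",
    )
    mirna = ExpressionMatrix(
        _count_block(rng, mir_ids, mir_shift, mir_pair, is_case, pair_index, config, sample_ids),
        feature_class="miRNA",
        kind="count",
    )

    true_lm = list(zip(motif_lnc, motif_mir))
    true_mm = list(zip(motif_mir, motif_mrna))
    decoy_lm = _decoy_edges(rng, lnc_ids, mir_ids, set(true_lm), config.db_decoy_rate)
    decoy_mm = _decoy_edges(rng, mir_ids, mrna_ids, set(true_mm), config.db_decoy_rate)

    def build_db(edge_type, true_edges, decoy_edges):
        la, lb = DB_LABELS[edge_type]
        rows = []
        for s, t in true_edges:  # planted edges appear in both labels
            rows.append((s, t, la))
            rows.append((s, t, lb))
        for s, t in decoy_edges:
            rows.append((s, t, la if rng.random() < 0.5 else lb))
        edges = pd.DataFrame(rows, columns=["source_id", "target_id", "db_name"])
        return TargetDB(edges=edges, edge_type=edge_type)

    lnc_mir_db = build_db(LNC_MIR, true_lm, decoy_lm)
    mir_mrna_db = build_db(MIR_MRNA, true_mm, decoy_mm)

    de_direction = {f: "none" for f in lnc_ids + mrna_ids + mir_ids}
    if config.effect_log2fc > 0:
        for f, s in zip(motif_lnc, motif_sign):
            de_direction[f] = "up" if s > 0 else "down"
        for f, s in zip(motif_mrna, motif_sign):
            de_direction[f] = "up" if s > 0 else "down"
        for f, s in zip(motif_mir, motif_sign):
            de_direction[f] = "down" if s > 0 else "up"

    db_rows = (
        [(LNC_MIR, s, t, "true") for s, t in true_lm]
        + [(LNC_MIR, s, t, "decoy") for s, t in decoy_lm]
        + [(MIR_MRNA, s, t, "true") for s, t in true_mm]
        + [(MIR_MRNA, s, t, "decoy") for s, t in decoy_mm]
    )
    truth = TruthTable(
        triples=list(zip(motif_lnc, motif_mir, motif_mrna)),
        de_direction=de_direction,
        db_edges=pd.DataFrame(
            db_rows, columns=["edge_type", "source_id", "target_id", "status"]
        ),
    )
    return SyntheticCohort(lnc, mrna, mirna, lnc_mir_db, mir_mrna_db, truth, samples, config)


def expand_probes(
    matrix: ExpressionMatrix, config: CohortConfig
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expand a transcript-level intensity matrix into probe-level rows.

    Each transcript is represented by 1-5 probes (uniform over the configured
    range) with independent multiplicative log-normal noise of SD
    ``probe_sigma`` (log2 scale).  Returns the probe matrix and a probe map
    with columns ``probe_id``, ``transcript_id``.  Counts are rejected:
    probes are a microarray concept.
    """
    if matrix.kind != "intensity":
        raise ValidationError("probes apply to intensity (array) matrices only")
    rng = np.random.default_rng(config.seed + 104729)  # offset stream from cohort
    lo, hi = config.probes_per_transcript
    probe_ids, transcript_of, blocks = [], [], []
    for t in matrix.feature_ids:
        k = int(rng.integers(lo, hi + 1))
        row = matrix.values.loc[t].to_numpy(dtype=float)
        noise = rng.normal(0.0, config.probe_sigma, size=(k, len(row)))
        blocks.append(row[None, :] * 2.0 ** noise)
        for j in range(1, k + 1):
            probe_ids.append(f"{t}__p{j}")
            transcript_of.append(t)
    values = pd.DataFrame(
        np.vstack(blocks), index=probe_ids, columns=matrix.sample_ids
    )
    probe_matrix = ExpressionMatrix(values, matrix.feature_class, "intensity")
    probe_map = pd.DataFrame(
        {"probe_id": probe_ids, "transcript_id": transcript_of}
    )
    return probe_matrix, probe_map


def write_dataset(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort to disk as TSV matrices, sample sheet, DB TSVs and
    a truth JSON.  Creates the directory if missing; values keep 12
    significant digits so a reload is numerically faithful."""
    from . import io as cio  # local import to avoid cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "lncrna": directory / "lncrna_intensity.tsv",
        "mrna": directory / "mrna_intensity.tsv",
        "mirna": directory / "mirna_counts.tsv",
        "samples": directory / "samples.tsv",
        "lnc_mir_db": directory / "lnc_mir_targets.tsv",
        "mir_mrna_db": directory / "mir_mrna_targets.tsv",
        "truth": directory / "truth.json",
    }
    cio.write_expression(cohort.lncrna, paths["lncrna"])
    cio.write_expression(cohort.mrna, paths["mrna"])
    cio.write_expression(cohort.mirna, paths["mirna"])
    cio.write_tsv(cohort.samples, paths["samples"])
    cio.write_tsv(cohort.lnc_mir_db.edges, paths["lnc_mir_db"])
    cio.write_tsv(cohort.mir_mrna_db.edges, paths["mir_mrna_db"])
    paths["truth"].write_text(json.dumps(cohort.truth.to_dict(), indent=1))
    return paths


def read_dataset(directory: str | Path) -> SyntheticCohort:
    """Reload a cohort written by :func:`write_dataset`."""
    from . import io as cio
    from .targets import load_target_db

    directory = Path(directory)
    lnc = cio.read_expression(directory / "lncrna_intensity.tsv", "lncRNA", "intensity")
    mrna = cio.read_expression(directory / "mrna_intensity.tsv", "mRNA", "intensity")
    mirna = cio.read_expression(directory / "mirna_counts.tsv", "miRNA", "count")
    samples = cio.read_sample_sheet(directory / "samples.tsv")
    lm = load_target_db(directory / "lnc_mir_targets.tsv", LNC_MIR)
    mm = load_target_db(directory / "mir_mrna_targets.tsv", MIR_MRNA)
    truth = TruthTable.from_dict(json.loads((directory / "truth.json").read_text()))
    return SyntheticCohort(lnc, mrna, mirna, lm, mm, truth, samples, CohortConfig())
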