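"""One-command pipeline: DE -> co-expression -> targets -> network -> hubs.

``run_stages`` is the pure core: it takes in-memory matrices, sample sheet
and target DBs and returns every intermediate plus a count report.
``run_pipeline`` wraps it with file I/O driven by a :class:`PipelineConfig`
(loadable from YAML), writes per-stage TSVs, the network exports and a JSON
run report, and logs every threshold it applied.  Any stage failure is
re-raised as :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .coexpression import coexpressed_pairs
from .diffexpr import (
    cpm_normalize,
    de_filter_array,
    de_filter_counts,
    passing_features,
    quantile_normalize,
)
from .errors import PipelineError, ValidationError
from .matrix import ExpressionMatrix
from .network import (
    CeRNANetwork,
    assemble_triples,
    build_network,
    export_network,
    extract_subnetwork,
    hub_nodes,
    node_degrees,
)
from .targets import TargetDB, lncrna_mirna_pairs, mirna_mrna_pairs

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Screening thresholds of the pipeline, with the standard defaults."""

    fc: float = 1.5
    p: float = 0.05
    r: float = 0.9
    coexp_p: float = 0.05
    neg_max: float = 0.0
    hub_fraction: float = 0.10
    paired: bool = True
    combine: str = "union"
    include_ties: bool = True

    def __post_init__(self) -> None:
        if self.fc < 1:
            raise ValidationError("fc threshold must be >= 1")
        for name in ("p", "coexp_p"):
            if not 0 < getattr(self, name) <= 1:
                raise ValidationError(f"{name} threshold must be in (0, 1]")
        if not -1.0 <= self.r <= 1.0:
            raise ValidationError("r threshold must be in [-1, 1]")
        if not -1.0 <= self.neg_max <= 1.0:
            raise ValidationError("neg_max must be in [-1, 1]")
        if not 0 < self.hub_fraction <= 1:
            raise ValidationError("hub_fraction must be in (0, 1]")
        if self.combine not in ("union", "intersection"):
            raise ValidationError("combine must be 'union' or 'intersection'")


@dataclass
class PipelineConfig:
    """File paths plus thresholds for a full run."""

    lncrna: str
    mrna: str
    mirna: str
    samples: str
    lnc_mir_dbs: list[str]
    mir_mrna_dbs: list[str]
    out_dir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        return Path(path)


@dataclass
class StageResults:
    de_lnc: pd.DataFrame
    de_mrna: pd.DataFrame
    de_mirna: pd.DataFrame
    coexp: pd.DataFrame
    lm_pairs: pd.DataFrame
    mm_pairs: pd.DataFrame
    triples: list
    network: CeRNANetwork
    degrees: pd.DataFrame
    hubs: list[str]
    subnetwork: CeRNANetwork
    report: dict


def _de_census(table: pd.DataFrame) -> dict:
    passing = table[table["passes"]]
    return {
        "total": int(len(table)),
        "pass": int(len(passing)),
        "up": int((passing["direction"] == "up").sum()),
        "down": int((passing["direction"] == "down").sum()),
        "untestable": int(table["untestable"].sum()),
    }


def run_stages(
    lnc: ExpressionMatrix,
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    samples: pd.DataFrame,
    lm_dbs: list[TargetDB],
    mm_dbs: list[TargetDB],
    thresholds: Thresholds | None = None,
) -> StageResults:
    """Run every analysis stage in memory and return all intermediates."""
    thr = thresholds or Thresholds()
    stage = "normalize"
    try:
        lnc_n = quantile_normalize(lnc)
        mrna_n = quantile_normalize(mrna)
        mir_log = cpm_normalize(mirna)

        stage = "differential_expression"
        logger.info("DE thresholds: FC >= %s, p < %s, paired=%s",
                    thr.fc, thr.p, thr.paired)
        de_lnc = de_filter_array(lnc_n, samples, thr.fc, thr.p, thr.paired)
        de_mrna = de_filter_array(mrna_n, samples, thr.fc, thr.p, thr.paired)
        de_mirna = de_filter_counts(mirna, samples, thr.fc, thr.p, thr.paired)
        lnc_ids = passing_features(de_lnc)
        mrna_ids = passing_features(de_mrna)
        mir_ids = passing_features(de_mirna)

        stage = "coexpression"
        logger.info("co-expression thresholds: r >= %s, p < %s", thr.r, thr.coexp_p)
        coexp = coexpressed_pairs(
            lnc_n, mrna_n, lnc_ids, mrna_ids, thr.r, thr.coexp_p
        )

        stage = "targets"
        logger.info("target DB combine rule: %s", thr.combine)
        lm = lncrna_mirna_pairs(lnc_ids, mir_ids, lm_dbs, thr.combine)
        mm = mirna_mrna_pairs(mir_ids, mrna_ids, mm_dbs, thr.combine)

        stage = "assemble_triples"
        triples = assemble_triples(
            coexp, lm, mm, lnc_n, mir_log, mrna_n, thr.neg_max
        )

        stage = "network"
        net = build_network(triples)
        degrees = node_degrees(net)

        stage = "hubs"
        if net.graph.number_of_nodes() > 0:
            ranking = hub_nodes(net, thr.hub_fraction, thr.include_ties)
            hubs = ranking.selected
            sub = extract_subnetwork(net, hubs)
        else:
            hubs = []
            sub = build_network([])
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(stage, exc) from exc

    report = {
        "thresholds": dataclasses.asdict(thr),
        "de": {
            "lncRNA": _de_census(de_lnc),
            "mRNA": _de_census(de_mrna),
            "miRNA": _de_census(de_mirna),
        },
        "pairs": {
            "coexpressed_lnc_mrna": int(len(coexp)),
            "lncrna_mirna": int(len(lm)),
            "mirna_mrna": int(len(mm)),
        },
        "triples": [list(t.ids) for t in triples],
        "n_triples": len(triples),
        "network": net.census(),
        "hubs": hubs,
        "subnetwork": sub.census(),
    }
    return StageResults(
        de_lnc, de_mrna, de_mirna, coexp, lm, mm, triples, net, degrees,
        hubs, sub, report,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """File-driven pipeline run; returns the JSON-serializable run report."""
    from .targets import load_target_db

    stage = "load"
    try:
        lnc = cio.read_expression(config.lncrna, "lncRNA", "intensity")
        mrna = cio.read_expression(config.mrna, "mRNA", "intensity")
        mirna = cio.read_expression(config.mirna, "miRNA", "count")
        samples = cio.read_sample_sheet(config.samples)
        lm_dbs = [load_target_db(p, "lncRNA->miRNA") for p in config.lnc_mir_dbs]
        mm_dbs = [load_target_db(p, "miRNA->mRNA") for p in config.mir_mrna_dbs]
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    res = run_stages(lnc, mrna, mirna, samples, lm_dbs, mm_dbs, config.thresholds)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_tsv(res.de_lnc, out / "de_lncrna.tsv")
    cio.write_tsv(res.de_mrna, out / "de_mrna.tsv")
    cio.write_tsv(res.de_mirna, out / "de_mirna.tsv")
    cio.write_tsv(res.coexp, out / "coexpressed_pairs.tsv")
    cio.write_tsv(res.lm_pairs, out / "lncrna_mirna_pairs.tsv")
    cio.write_tsv(res.mm_pairs, out / "mirna_mrna_pairs.tsv")
    triples_df = pd.DataFrame(
        [dataclasses.asdict(t) for t in res.triples],
        columns=["lncrna", "mirna", "mrna", "r_lnc_mrna", "r_mir_lnc", "r_mir_mrna"],
    )
    cio.write_tsv(triples_df, out / "triples.tsv")
    export_network(res.network, out / "network")
    export_network(res.subnetwork, out / "subnetwork")
    cio.write_tsv(
        pd.DataFrame({"hub": res.hubs}), out / "hubs.tsv"
    )
    (out / "report.json").write_text(json.dumps(res.report, indent=1))
    return res.report
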