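"""End-to-end pipeline: simulate or load tables, preprocess, diversity,
ordination and group inference, habitat classification, coupling, and the
co-occurrence network, driven by a single strict-schema YAML config and
summarised in a machine-readable run report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .beta import anova_tukey, bray_curtis, nmds, permanova
from .containers import SampleFrame, Stratum, StratumScheme, default_scheme
from .coupling import abundant_flow, habitat_abundance_regression, taxon_habitat_fractions
from .diversity import alpha_summary
from .network import cooccurrence_network, write_edgelist_graphml, write_edgelist_tsv
from .partition import class_summary, classify_otus, presence_matrix, venn_partition
from .preprocess import filter_table, rarefy, to_relative
from .simulate import SimParams, generate_community, generate_paired_euk_table

log = logging.getLogger("nodulebiome")

_TOP_KEYS = {
    "simulate", "inputs", "scheme", "rarefaction_depth", "permutations",
    "rule_set", "min_count", "min_samples", "nmds", "network",
    "coupling_pairs", "taxon_patterns", "flow_source", "flow_threshold",
    "seed", "out_dir",
}
_INPUT_KEYS = {"count_table", "sample_frame", "euk_table", "dialect"}
_NMDS_KEYS = {"k", "n_restarts", "max_iter", "tol"}
_NETWORK_KEYS = {"n_permutations", "fdr_alpha", "min_prevalence", "min_abs_rho"}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline configuration. Exactly one of ``simulate`` /
    ``inputs`` must be present; unknown keys are rejected."""

    raw: dict
    seed: int = 0
    out_dir: Path = Path("nodulebiome_out")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        has_sim = "simulate" in d
        has_in = "inputs" in d
        if has_sim == has_in:
            raise ConfigError("config must contain exactly one of 'simulate' or 'inputs'")
        if has_in:
            unknown = set(d["inputs"]) - _INPUT_KEYS
            if unknown:
                raise ConfigError(f"unknown inputs keys: {sorted(unknown)}")
            for req in ("count_table", "sample_frame"):
                if req not in d["inputs"]:
                    raise ConfigError(f"inputs block missing {req!r}")
        if "nmds" in d:
            unknown = set(d["nmds"]) - _NMDS_KEYS
            if unknown:
                raise ConfigError(f"unknown nmds keys: {sorted(unknown)}")
        if "network" in d:
            unknown = set(d["network"]) - _NETWORK_KEYS
            if unknown:
                raise ConfigError(f"unknown network keys: {sorted(unknown)}")
        return cls(raw=d, seed=int(d.get("seed", 0)), out_dir=Path(d.get("out_dir", "nodulebiome_out")))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(d)

    def scheme(self) -> StratumScheme:
        if "scheme" not in self.raw:
            return default_scheme()
        strata = []
        for entry in self.raw["scheme"]:
            strata.append(
                Stratum(
                    entry["label"], entry["habitat"],
                    entry.get("lower"), entry.get("upper"),
                )
            )
        return StratumScheme(tuple(strata))

    def sim_params(self) -> SimParams:
        block = dict(self.raw.get("simulate") or {})
        block.setdefault("seed", self.seed)
        block["strata"] = self.scheme()
        return SimParams(**block)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunReport:
    config_echo: dict
    seed: int
    stages: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    wall_seconds: float | None = None

    def as_dict(self) -> dict:
        return {
            "config_echo": self.config_echo,
            "seed": self.seed,
            "stages": self.stages,
            "checksums": self.checksums,
            "wall_seconds": self.wall_seconds,
        }


def run_pipeline(config: PipelineConfig, record_wall_time: bool = False) -> RunReport:
    """Execute the full pipeline and write all artifacts into
    ``config.out_dir``. A rerun with the same config produces bit-identical
    artifacts (wall-time recording is off by default so the report itself is
    reproducible too)."""
    t0 = time.time()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme()
    seed = config.seed
    report = RunReport(config_echo=_echo(config.raw), seed=seed)

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        report.checksums[name] = _sha256(path)

    stage = "load"
    try:
        euk_table = None
        truth = None
        if "simulate" in config.raw:
            stage = "simulate"
            params = config.sim_params()
            table, frame, truth = generate_community(params)
            if params.n_euk_otus > 0:
                euk_table, truth = generate_paired_euk_table(params, truth, frame)
            _write("counts.tsv", lambda p: nio.write_count_table(table, p))
            _write("samples.tsv", lambda p: nio.write_sample_frame(frame, p))
            _write("truth.json", lambda p: nio.write_json(truth.as_dict(), p))
            if euk_table is not None:
                _write("euk_counts.tsv", lambda p: nio.write_count_table(euk_table, p))
            report.stages["simulate"] = {"status": "ok", "seed": params.seed,
                                         "n_otus": table.shape[0], "n_samples": table.shape[1]}
        else:
            inputs = config.raw["inputs"]
            dialect = inputs.get("dialect", "wide-tsv")
            table = nio.read_count_table(inputs["count_table"], dialect)
            frame = nio.read_sample_frame(inputs["sample_frame"])
            if inputs.get("euk_table"):
                euk_table = nio.read_count_table(inputs["euk_table"], dialect)
            report.stages["load"] = {"status": "ok", "n_otus": table.shape[0],
                                     "n_samples": table.shape[1]}
        frame.validate_against(scheme)

        stage = "filter"
        filtered, filt_report = filter_table(table, frame, return_report=True)
        report.stages["filter"] = {"status": "ok", **filt_report.as_dict()}
        noncontrol = frame.subset([s for s in frame.noncontrol_samples()
                                   if s in filtered.counts.columns])

        stage = "normalize"
        rel = to_relative(filtered)
        report.stages["normalize"] = {"status": "ok"}

        stage = "rarefy"
        depth = int(config.raw.get("rarefaction_depth", 5000))
        rarefied, rare_report = rarefy(filtered, depth, seed, return_report=True)
        _write("rarefied_counts.tsv", lambda p: nio.write_count_table(rarefied, p))
        report.stages["rarefy"] = {"status": "ok", **rare_report.as_dict()}

        stage = "alpha"
        alpha = alpha_summary(filtered, noncontrol, depth=depth, seed=seed)
        _write("alpha_per_sample.tsv", lambda p: alpha.per_sample.to_csv(p, sep="\t"))
        _write("alpha_per_group.tsv", lambda p: alpha.per_group.to_csv(p, sep="\t"))
        report.stages["alpha"] = {
            "status": "ok", "seed": seed, "depth": depth,
            "dropped_samples": alpha.dropped_samples,
            "empty_groups": [list(g) for g in alpha.empty_groups],
        }

        stage = "beta"
        dist = bray_curtis(rel)
        _write("bray_curtis.tsv", lambda p: dist.to_frame().to_csv(p, sep="\t"))
        nmds_cfg = config.raw.get("nmds", {})
        ord_res = nmds(
            dist,
            k=int(nmds_cfg.get("k", 2)),
            n_restarts=int(nmds_cfg.get("n_restarts", 4)),
            max_iter=int(nmds_cfg.get("max_iter", 150)),
            tol=float(nmds_cfg.get("tol", 1e-6)),
            seed=seed,
        )
        _write("nmds_coordinates.tsv", lambda p: ord_res.coordinates.to_csv(p, sep="\t"))
        n_perm = int(config.raw.get("permutations", 999))
        habitats = noncontrol.data.loc[dist.sample_ids, "habitat"]
        perma = permanova(dist, habitats, n_permutations=n_perm, seed=seed)
        beta_json: dict[str, Any] = {
            "nmds_stress": ord_res.stress,
            "nmds_converged": ord_res.converged,
            "permanova_habitat": {
                "pseudo_F": perma.pseudo_F, "R2": perma.R2, "p_value": perma.p_value,
                "df_between": perma.df_between, "df_within": perma.df_within,
                "n_permutations": perma.n_permutations,
            },
        }
        try:
            at = anova_tukey(
                alpha.per_sample["shannon"],
                alpha.per_sample["area"],
                alpha.per_sample["stratum"],
            )
            beta_json["anova_shannon"] = {
                "table": json.loads(at.anova_table.to_json()),
                "residual_df": at.residual_df,
                "tukey": at.tukey_table.to_dict(orient="records"),
            }
        except Exception as exc:  # single-area designs etc.
            beta_json["anova_shannon"] = {"status": "skipped", "reason": str(exc)}
        _write("beta_results.json", lambda p: nio.write_json(beta_json, p))
        report.stages["beta"] = {"status": "ok", "seed": seed,
                                 "n_permutations": n_perm, "stress": ord_res.stress}

        stage = "classify"
        pres = presence_matrix(
            filtered, noncontrol, scheme,
            min_count=int(config.raw.get("min_count", 1)),
            min_samples=int(config.raw.get("min_samples", 1)),
        )
        venn = venn_partition(pres, scheme)
        _write("venn.json", lambda p: nio.write_json(venn.as_dict(), p))
        cls = classify_otus(
            pres, scheme, rule_set=config.raw.get("rule_set", "operative"),
            occupancy_table=filtered, frame=noncontrol,
        )
        cls_df = pd.DataFrame(
            {
                "label": cls.labels,
                "habitat": cls.specialist_habitat.reindex(cls.labels.index),
                "stratum": cls.specialist_stratum.reindex(cls.labels.index),
                "occupancy": cls.occupancy,
            }
        )
        cls_df.index.name = "otu_id"
        _write("classification.tsv", lambda p: cls_df.to_csv(p, sep="\t"))
        summary = class_summary(cls, filtered, noncontrol)
        _write("class_summary.tsv", lambda p: summary.per_class.to_csv(p, sep="\t"))
        report.stages["classify"] = {
            "status": "ok", "rule_set": cls.rule_set,
            "dropped_otus": len(pres.dropped_otus),
            "empty_strata": pres.empty_strata,
        }

        stage = "coupling"
        pairs = [tuple(p.split(":")) for p in config.raw.get(
            "coupling_pairs", ["epipelagic:nodule", "epipelagic:sed_0_5"])]
        pairs = [(a, b) for a, b in pairs if a in scheme and b in scheme]
        coup = habitat_abundance_regression(rel, noncontrol, scheme, pairs)
        _write("coupling_regressions.tsv", lambda p: coup.as_frame().to_csv(p, sep="\t", index=False))
        fractions = {}
        for pat in config.raw.get("taxon_patterns", ["Cyanobacteria"]):
            try:
                fractions[pat] = taxon_habitat_fractions(filtered, noncontrol, pat).to_dict()
            except Exception as exc:
                fractions[pat] = {"status": "skipped", "reason": str(exc)}
        _write("taxon_fractions.json", lambda p: nio.write_json(fractions, p))
        source = config.raw.get("flow_source", "epipelagic")
        if source in scheme:
            flow = abundant_flow(rel, noncontrol, scheme, source,
                                 threshold=float(config.raw.get("flow_threshold", 0.01)))
            _write("abundant_flow.tsv", lambda p: flow.mean_abundance.to_csv(p, sep="\t"))
        report.stages["coupling"] = {"status": "ok", "pairs": [list(p) for p in pairs]}

        stage = "network"
        if euk_table is not None:
            net_cfg = config.raw.get("network", {})
            euk_rel = to_relative(euk_table)
            edge_list = cooccurrence_network(
                rel, euk_rel,
                n_permutations=int(net_cfg.get("n_permutations", 999)),
                fdr_alpha=float(net_cfg.get("fdr_alpha", 0.05)),
                min_prevalence=float(net_cfg.get("min_prevalence", 0.2)),
                min_abs_rho=float(net_cfg.get("min_abs_rho", 0.0)),
                seed=seed,
            )
            _write("network_edges.tsv", lambda p: write_edgelist_tsv(edge_list, p))
            _write("network.graphml", lambda p: write_edgelist_graphml(edge_list, p))
            report.stages["network"] = {
                "status": "ok", "seed": seed, "n_edges": len(edge_list.edges),
                "n_tested": edge_list.n_tested,
            }
        else:
            report.stages["network"] = {"status": "skipped", "reason": "no eukaryote table"}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if record_wall_time:
        report.wall_seconds = time.time() - t0
    nio.write_json(report.as_dict(), out / "report.json")
    report.checksums["report.json"] = _sha256(out / "report.json")
    return report


def _echo(raw: dict) -> dict:
    """JSON-safe copy of the raw config, minus the output location (so two
    runs of the same analysis into different directories report identically)."""
    echo = {k: v for k, v in raw.items() if k != "out_dir"}
    return json.loads(json.dumps(echo, default=str))
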