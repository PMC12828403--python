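"""End-to-end orchestration: merge -> interfaces -> consensus -> chamber; peptides.

A run is described by a single plain-text (YAML) config.  Every threshold
the analyses use is echoed into the machine-readable run report, so a report
fully documents the parameters that produced it; reports carry no
timestamps, making reruns of an identical config bitwise identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import docksite, paralogpep, refmap, rigid, structio, synthdata

__all__ = ["RunConfig", "RunReport", "run_pipeline", "summarize_membership"]

DEFAULT_THRESHOLDS = {
    "contact": 4.5,
    "hbond": 3.5,
    "tau": docksite.DEFAULT_TAU,
    "burial": 5.0,
}

STAGE_ORDER = ["simulate", "merge", "interfaces", "consensus", "chamber", "peptides"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    registry: str = "default"
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds or {})
        self.thresholds = merged
        for name, value in self.thresholds.items():
            if not value > 0:
                raise ConfigError(f"threshold {name} must be positive, got {value}")
        if self.registry != "default" and not Path(self.registry).exists():
            raise ConfigError(f"registry file not found: {self.registry}")
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for stage, cfg in self.stages.items():
            for key in ("frag1", "frag2", "model", "peptides_file", "fasta"):
                p = (cfg or {}).get(key)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"stage {stage}: missing input {key}: {p}")

    def load_registry(self) -> refmap.DomainRegistry:
        if self.registry == "default":
            return refmap.default_registry()
        return refmap.load_registry(self.registry)


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    manifest: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "stages": self.stages,
             "manifest": sorted(self.manifest), "warnings": self.warnings},
            indent=2, sort_keys=True, default=_jsonable,
        )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def summarize_membership(results: list[docksite.ConsensusResult]) -> pd.DataFrame:
    """Paralog x enzyme occupancy matrix from per-enzyme consensus results.

    Cells hold booleans (has the consensus pose); per-enzyme pose counts are
    provided as ``<enzyme>_n_poses`` columns, and the final row ``TOTAL``
    gives per-enzyme carrier counts.
    """
    if not results:
        raise ValueError("no consensus results")
    enzymes = [r.enzyme for r in results]
    if len(enzymes) != len(set(enzymes)):
        raise ValueError(f"duplicate enzyme results: {enzymes}")
    paralogs = sorted({p for r in results for p in r.membership})
    data = {}
    for r in results:
        data[r.enzyme] = [r.membership.get(p, {}).get("has_consensus", False)
                          for p in paralogs]
        data[f"{r.enzyme}_n_poses"] = [r.membership.get(p, {}).get("n_poses", 0)
                                       for p in paralogs]
    df = pd.DataFrame(data, index=paralogs)
    totals = {r.enzyme: int(df[r.enzyme].sum()) for r in results}
    for r in results:
        totals[f"{r.enzyme}_n_poses"] = int(df[f"{r.enzyme}_n_poses"].sum())
    df.loc["TOTAL"] = pd.Series(totals)
    return df


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    A stage failure marks the stage failed and skips everything downstream;
    the report is written either way.  Reruns with identical config and
    inputs produce identical reports.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={
        "outdir": str(config.outdir), "seed": config.seed,
        "registry": config.registry, "thresholds": config.thresholds,
        "stages": config.stages,
    })
    registry = config.load_registry()
    state: dict = {"consensus_results": [], "failed": False}

    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        if state["failed"]:
            report.stages[stage] = {"status": "skipped"}
            continue
        cfg = config.stages[stage] or {}
        try:
            outputs = _STAGE_FUNCS[stage](cfg, config, registry, state, outdir, report)
            report.stages[stage] = {"status": "ok", "parameters": cfg, **outputs}
        except Exception as exc:  # noqa: BLE001 - report and halt downstream
            report.stages[stage] = {"status": "failed", "parameters": cfg,
                                    "error": f"{type(exc).__name__}: {exc}"}
            state["failed"] = True

    report_path = outdir / "report.json"
    report_path.write_text(report.to_json())
    report.manifest.append(str(report_path))
    return report


def _write(report: RunReport, path: Path, text: str) -> str:
    path.write_text(text)
    report.manifest.append(str(path))
    return str(path)


def _stage_simulate(cfg, config, registry, state, outdir, report):
    out = {}
    if "poses" in cfg:
        specs = cfg["poses"] if isinstance(cfg["poses"], list) else [cfg["poses"]]
        ensembles = []
        for i, raw in enumerate(specs):
            kw = dict(raw or {})
            kw.setdefault("seed", config.seed + i)
            ensembles.append(synthdata.make_pose_ensemble(synthdata.PoseEnsembleSpec(**kw)))
        state["ensembles"] = ensembles
        out["n_ensembles"] = len(ensembles)
    if "paralogs" in cfg:
        kw = dict(cfg["paralogs"] or {})
        kw.setdefault("seed", config.seed)
        state["paralog_pair"] = synthdata.make_paralog_pair(synthdata.ParalogPairSpec(**kw))
        out["paralog_pair_length"] = len(state["paralog_pair"][0])
    if "fragments" in cfg:
        kw = dict(cfg["fragments"] or {})
        dimer_kw = kw.pop("dimer", {"domains": [["KS", 60], ["AT", 60], ["DH", 60]]})
        dimer_kw.setdefault("seed", config.seed)
        dimer_kw["domains"] = [tuple(d) for d in dimer_kw["domains"]]
        parent, meta = synthdata.make_dimer(synthdata.SynthDimerSpec(**dimer_kw))
        rng = np.random.default_rng(config.seed)
        frag1, frag2, truth = synthdata.make_fragment_pair(
            parent,
            junction=kw.get("junction", meta["domain_ranges"]["AT"][1]),
            shared_span=meta["domain_ranges"]["KS"],
            transform2=synthdata.random_transform(rng),
            noise_sigma=kw.get("noise_sigma", 0.3),
            seed=config.seed,
        )
        state["fragments"] = (frag1, frag2, truth, synthdata.dimer_registry(meta))
        out["fragment_parent_residues"] = parent.n_residues()
    return out


def _stage_merge(cfg, config, registry, state, outdir, report):
    if "frag1" in cfg:
        frag1 = structio.read_structure(cfg["frag1"])
        frag2 = structio.read_structure(cfg["frag2"])
        reg = registry
    elif "fragments" in state:
        frag1, frag2, _, reg = state["fragments"]
    else:
        raise ConfigError("merge stage needs frag1/frag2 files or a simulated fragment pair")
    spec = rigid.FragmentSpec(junction=cfg.get("junction", 935),
                              superpose_on=cfg.get("superpose_on", "KS"))
    merged = rigid.merge_fragments(frag1, frag2, spec, reg)
    state["merged"] = merged
    path = str(structio.write_structure(merged.model, outdir / "merged.cif", "mmcif"))
    report.manifest.append(path)
    _write(report, outdir / "junction.json",
           json.dumps(merged.junction_report, indent=2, sort_keys=True, default=_jsonable))
    return {"junction_report": merged.junction_report, "model_file": path}


def _stage_interfaces(cfg, config, registry, state, outdir, report):
    if "model" in cfg:
        model = structio.read_structure(cfg["model"])
    elif "merged" in state:
        model = state["merged"].model
    else:
        raise ConfigError("interfaces stage needs a model file or an upstream merge")
    cutoff = config.thresholds["contact"]
    rows = []
    for pair in cfg.get("pairs", []):
        dom_a, dom_b = pair
        for chain_id in model.chain_ids():
            ra = registry.positions(dom_a)
            rb = registry.positions(dom_b)
            sel_a = structio.select(model, chain_id, (min(ra), max(ra)))
            sel_b = structio.select(model, chain_id, (min(rb), max(rb)))
            from .interface import find_contacts

            for c in find_contacts(model, sel_a, sel_b, cutoff):
                rows.append({"domain_a": dom_a, "domain_b": dom_b, "chain": chain_id,
                             "resnum_a": c.resnum_a, "resname_a": c.resname_a,
                             "resnum_b": c.resnum_b, "resname_b": c.resname_b,
                             "min_distance": round(c.min_distance, 3),
                             "n_atom_pairs": c.n_atom_pairs,
                             "salt_bridge": c.salt_bridge})
    df = pd.DataFrame(rows)
    path = _write(report, outdir / "contacts.tsv", df.to_csv(sep="\t", index=False))
    return {"n_contacts": len(rows), "contacts_file": path}


def _stage_consensus(cfg, config, registry, state, outdir, report):
    if "ensembles" not in state:
        raise ConfigError("consensus stage needs simulated ensembles (stage simulate.poses)")
    tau = cfg.get("tau", config.thresholds["tau"])
    results = []
    for ens in state["ensembles"]:
        poses = []
        for rec in ens["records"]:
            poses.append(docksite.extract_pose(
                rec["model"], ens["spec"].enzyme, ens["registry"], ens["canonical"],
                paralog=rec["paralog"], source_id=rec["source_id"])[0])
        clusters = docksite.cluster_poses(poses, tau)
        results.append(docksite.consensus_site(clusters, poses, tau))
    state["consensus_results"] = results
    matrix = summarize_membership(results)
    path = _write(report, outdir / "membership.tsv", matrix.to_csv(sep="\t"))
    carriers = {r.enzyme: r.n_carriers() for r in results}
    return {"carrier_counts": carriers, "membership_file": path, "tau": tau}


def _stage_chamber(cfg, config, registry, state, outdir, report):
    results = state.get("consensus_results")
    if not results:
        raise ConfigError("chamber stage needs upstream consensus results")
    anchors = {}
    for r in results:
        ser = r.consensus.medoid.serine_ca
        if ser is not None:
            anchors[r.enzyme] = ser
    summary = docksite.chamber_summary(anchors)
    path = _write(report, outdir / "chamber.json", json.dumps(
        {"chambers": summary.chambers, "parameters": summary.parameters},
        indent=2, sort_keys=True, default=_jsonable))
    return {"chamber_file": path,
            "hull_volume": summary.chambers[0]["hull_volume"],
            "max_displacement": summary.chambers[0]["max_displacement"]}


def _stage_peptides(cfg, config, registry, state, outdir, report):
    if "peptides_file" in cfg:
        peps = [line.strip() for line in Path(cfg["peptides_file"]).read_text().splitlines()
                if line.strip()]
        from Bio import SeqIO

        records = list(SeqIO.parse(cfg["fasta"], "fasta"))
        if len(records) < 2:
            raise ConfigError("peptides stage needs a 2-record paralog FASTA")
        pa = (records[0].id, str(records[0].seq))
        pb = (records[1].id, str(records[1].seq))
        detected = peps
    elif "paralog_pair" in state:
        seq_a, seq_b, detected, _ = state["paralog_pair"]
        pa, pb = ("paralog_a", seq_a), ("paralog_b", seq_b)
    else:
        raise ConfigError("peptides stage needs a peptides file or a simulated paralog pair")
    classes, summary = paralogpep.classify_peptides(
        detected, pa, pb, collapse_il=cfg.get("collapse_il", False))
    aln = refmap.global_align(pa[1], pb[1])
    identity = refmap.percent_identity(aln)
    rows = [{"peptide": c.peptide.sequence, "occurrences_a": c.occurrences_a,
             "occurrences_b": c.occurrences_b, "verdict": c.verdict,
             "multiplicity": c.multiplicity} for c in classes]
    path = _write(report, outdir / "peptide_classes.tsv",
                  pd.DataFrame(rows).to_csv(sep="\t", index=False))
    return {"summary": summary, "percent_identity": identity, "classes_file": path}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "merge": _stage_merge,
    "interfaces": _stage_interfaces,
    "consensus": _stage_consensus,
    "chamber": _stage_chamber,
    "peptides": _stage_peptides,
}
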