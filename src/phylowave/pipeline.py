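"""End-to-end synthetic pipeline: generate -> filter -> profile -> rateshift
-> trace -> map3d -> mds, with a machine-readable, fully deterministic report.

The pipeline exercises every stage of the analysis on generated data with
planted truth and aggregates counts into a versioned JSON report (no
timestamps, so reruns with one seed are byte-identical). A single global
seed is fanned out to per-stage seeds by stable hashing, so stages can be
rerun independently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

from pydantic import BaseModel, ConfigDict

from . import rateshift as rs
from . import structmap as sm
from . import synthetic as syn
from . import topology
from .profiler import profile_hits, refine, scan
from .seqcore import greedy_filter, write_fasta, write_labels

SCHEMA_VERSION = 1


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MsaSection(_Section):
    n_per_group: int = 20
    n_type_ii: int = 10
    n_type_i: int = 10
    n_null: int = 80
    gap_rate: float = 0.02


class SuccessionSection(_Section):
    n_groups: int = 5
    n_per_group: int = 12
    n_per_stage: int = 3
    length: int = 60
    gap_rate: float = 0.05


class FilterSection(_Section):
    enabled: bool = True
    threshold: float = 0.95


class ProfileSection(_Section):
    enabled: bool = True
    groups: list[str] = ["mca", "mcb"]
    n_members: int = 10
    decoys: int = 10
    rounds: int = 3


class RateshiftSection(_Section):
    enabled: bool = True
    c_hi: float = rs.C_HI
    c_lo: float = rs.C_LO
    grantham_min: float = rs.GRANTHAM_MIN
    B: int = rs.DEFAULT_B
    alpha: float = rs.DEFAULT_ALPHA


class StructureSection(_Section):
    enabled: bool = True
    cutoff: float = sm.DEFAULT_CONTACT_CUTOFF
    n_morphs: int = 8
    rotation_deg: float = 25.0


class TopologySection(_Section):
    enabled: bool = True
    counts: list[int] = [11, 12]


class PipelineConfig(_Section):
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "phylowave_out"
    msa: MsaSection = MsaSection()
    succession: SuccessionSection = SuccessionSection()
    filter: FilterSection = FilterSection()
    profile: ProfileSection = ProfileSection()
    rateshift: RateshiftSection = RateshiftSection()
    structure: StructureSection = StructureSection()
    topology: TopologySection = TopologySection()


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (below 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the configured stages in order, writing each stage's outputs
    before the next starts, and return the aggregated report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config.model_dump(),
        "stages": {},
    }

    state: dict[str, Any] = {}
    stages = [
        ("generate", _stage_generate),
        ("filter", _stage_filter),
        ("profile", _stage_profile),
        ("rateshift", _stage_rateshift),
        ("trace", _stage_trace),
        ("map3d", _stage_map3d),
        ("mds", _stage_mds),
    ]
    for name, fn in stages:
        try:
            summary = fn(config, outdir, state)
        except Exception as exc:  # halt with stage name; partial outputs kept
            raise PipelineError(name, exc) from exc
        if summary is not None:
            report["stages"][name] = summary
            _write_json(report, outdir / "report.json")
    return report


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Stages


def _stage_generate(config: PipelineConfig, outdir: Path, state: dict) -> dict:
    seed = derive_seed(config.seed, "generate")
    m = config.msa
    spec = syn.default_two_group_spec(
        seed, m.n_per_group, m.n_type_ii, m.n_type_i, m.n_null, m.gap_rate
    )
    aln, truth = syn.generate_msa(spec)
    write_fasta(aln.sequences, outdir / "msa.fa")
    write_labels(aln.labels, outdir / "labels.tsv")
    state["aln"], state["msa_truth"] = aln, truth

    s = config.succession
    sspec = syn.default_succession_spec(
        derive_seed(config.seed, "succession"),
        s.n_groups, s.n_per_group, s.n_per_stage, s.length, s.gap_rate,
    )
    saln, struth = syn.generate_msa(sspec)
    write_fasta(saln.sequences, outdir / "succession.fa")
    write_labels(saln.labels, outdir / "succession_labels.tsv")
    state["succession_aln"], state["succession_truth"] = saln, struth

    p = config.profile
    models = syn.default_segment_models(
        p.groups, derive_seed(config.seed, "scan_models")
    )
    db, db_truth = syn.generate_scan_db(
        p.n_members, models, p.decoys, derive_seed(config.seed, "scan_db")
    )
    write_fasta(db, outdir / "scan_db.fa")
    write_labels({s.id: s.taxon or "unknown" for s in db}, outdir / "scan_taxa.tsv")
    state["scan_models"], state["scan_db"], state["scan_truth"] = models, db, db_truth

    t = config.topology
    tms_seqs = [
        syn.generate_tms_sequence(
            n, derive_seed(config.seed, f"tms:{n}"), seq_id=f"tms_{n}"
        )
        for n in t.counts
    ]
    write_fasta(tms_seqs, outdir / "tms.fa")
    state["tms_seqs"] = tms_seqs

    st = config.structure
    sspec3d = syn.StructureSpec(rotation_deg=st.rotation_deg)
    model_a, model_b, colmap, s_truth = syn.generate_structures(
        sspec3d, derive_seed(config.seed, "structures")
    )
    sm.write_pdb_ca(model_a, outdir / "confA.pdb")
    sm.write_pdb_ca(model_b, outdir / "confB.pdb")
    state["structures"] = (model_a, model_b, colmap, s_truth)

    return {
        "msa_sequences": aln.n,
        "msa_columns": aln.length,
        "succession_sequences": saln.n,
        "scan_db_sequences": len(db),
        "tms_sequences": len(tms_seqs),
        "structure_sites": len(colmap.mapping),
    }


def _stage_filter(config: PipelineConfig, outdir: Path, state: dict) -> dict | None:
    if not config.filter.enabled:
        return None
    db = state["scan_db"]
    reps = greedy_filter(db, config.filter.threshold)
    write_fasta(reps, outdir / "representatives.fa")
    return {
        "input_sequences": len(db),
        "threshold": config.filter.threshold,
        "retained": len(reps),
    }


def _stage_profile(config: PipelineConfig, outdir: Path, state: dict) -> dict | None:
    if not config.profile.enabled:
        return None
    models, db, truth = state["scan_models"], state["scan_db"], state["scan_truth"]
    taxa = {s.id: s.taxon or "unknown" for s in db}
    summary: dict[str, Any] = {}
    for g, model in models.items():
        pattern = model.to_pattern()
        hits = scan(pattern, db)
        profile = profile_hits(hits, taxa)
        refined, status = refine(pattern, db, config.profile.rounds)
        member_ids = {sid for sid, grp in truth.scan_members.items() if grp == g}
        hit_ids = {h.seq_id for h in hits}
        (outdir / f"pattern_{g}.txt").write_text(refined.text + "\n")
        summary[g] = {
            "hits": len(hits),
            "specificity": profile.specificity(g),
            "member_recall": (
                len(member_ids & hit_ids) / len(member_ids) if member_ids else None
            ),
            "decoy_hits": sum(1 for h in hits if taxa[h.seq_id] == "decoy"),
            "refine_status": status,
        }
    return summary


def _stage_rateshift(config: PipelineConfig, outdir: Path, state: dict) -> dict | None:
    if not config.rateshift.enabled:
        return None
    r = config.rateshift
    aln = state["aln"]
    calls = rs.rate_shift_scan(
        aln, "g1", "g2",
        c_hi=r.c_hi, c_lo=r.c_lo, grantham_min=r.grantham_min,
        B=r.B, seed=derive_seed(config.seed, "rateshift"),
    )
    state["calls"] = calls
    with (outdir / "rateshift.tsv").open("w") as fh:
        fh.write("column\ttype\tD\tp\tq\n")
        for c in calls:
            fh.write(
                f"{c.column}\t{c.type}\t"
                f"{'' if c.D is None else f'{c.D:.4f}'}\t"
                f"{'' if c.p is None else f'{c.p:.6g}'}\t"
                f"{'' if c.q is None else f'{c.q:.6g}'}\n"
            )
    truth = state["msa_truth"]
    sig = [c for c in calls if c.q is not None and c.q <= r.alpha and c.type != "none"]
    by_type: dict[str, int] = {}
    for c in sig:
        by_type[c.type] = by_type.get(c.type, 0) + 1
    recovered = {
        kind: sum(
            1
            for c in sig
            if c.column in truth.sites
            and truth.sites[c.column].kind == kind
            and c.type == {"typeII": "II", "typeI": "I"}.get(kind)
        )
        for kind in ("typeII", "typeI")
    }
    planted = {
        kind: sum(1 for s in truth.sites.values() if s.kind == kind)
        for kind in ("typeII", "typeI")
    }
    return {
        "columns_tested": sum(1 for c in calls if c.p is not None),
        "significant_by_type": by_type,
        "type_ii_recovered": recovered["typeII"],
        "type_ii_planted": planted["typeII"],
        "type_i_recovered": recovered["typeI"],
        "type_i_planted": planted["typeI"],
    }


def _stage_trace(config: PipelineConfig, outdir: Path, state: dict) -> dict | None:
    saln, truth = state["succession_aln"], state["succession_truth"]
    profile = rs.conservation_profile(saln)
    stages = {
        col: rs.fixation_stage(saln, col, profile=profile)
        for col in range(1, saln.length + 1)
    }
    state["stages"] = stages
    with (outdir / "fixation.tsv").open("w") as fh:
        fh.write("column\tstage\tresidue\n")
        for col in sorted(stages):
            st = stages[col]
            fh.write(f"{col}\t{st.stage}\t{st.residue or ''}\n")
    planted = {c: s for c, s in truth.sites.items() if s.kind == "conserved_since_stage"}
    exact = sum(1 for c, s in planted.items() if stages[c].stage == s.stage)
    histogram: dict[str, int] = {}
    for st in stages.values():
        histogram[st.stage] = histogram.get(st.stage, 0) + 1
    return {
        "planted_staged_columns": len(planted),
        "exact_stage_recovery": exact,
        "stage_histogram": histogram,
    }


def _stage_map3d(config: PipelineConfig, outdir: Path, state: dict) -> dict | None:
    if not config.structure.enabled:
        return None
    model_a, model_b, colmap, truth = state["structures"]
    sites = sorted(colmap.mapping)
    cutoff = config.structure.cutoff
    net_a = sm.neighbor_network(model_a, colmap, sites, cutoff, "A")
    net_b = sm.neighbor_network(model_b, colmap, sites, cutoff, "B")
    state["networks"] = (net_a, net_b)
    import networkx as nx

    components = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(net_a.graph)),
        key=lambda c: c[0],
    )
    planted: dict[int, list[int]] = {}
    for col, cid in truth.structure_clusters.items():
        planted.setdefault(cid, []).append(col)
    planted_sets = sorted(
        (tuple(sorted(cols)) for cols in planted.values()), key=lambda c: c[0]
    )
    rearranged = [r.column for r in sm.compare_conformations(net_a, net_b) if r.rearranged]
    with (outdir / "network_A.tsv").open("w") as fh:
        fh.write("column_i\tcolumn_j\tdistance\n")
        for i, j, d in net_a.graph.edges.data("distance"):
            fh.write(f"{i}\t{j}\t{d:.3f}\n")
    return {
        "sites": len(sites),
        "edges_A": net_a.graph.number_of_edges(),
        "components_A": len(components),
        "clusters_recovered": components == planted_sets,
        "rearranged_sites": len(rearranged),
        "rmsd_A_B": sm.kabsch_rmsd(model_a.coords, model_b.coords),
    }


def _stage_mds(config: PipelineConfig, outdir: Path, state: dict) -> dict | None:
    if not config.structure.enabled:
        return None
    model_a, model_b, _, _ = state["structures"]
    morphs = syn.make_morphs(model_a, model_b, config.structure.n_morphs)
    embedding = sm.mds_map(morphs, [model_a.model_id, model_b.model_id])
    frame = embedding.to_frame()
    frame.to_csv(outdir / "conformer_map.tsv", sep="\t", index=False, float_format="%.6f")
    labels = {mid: embedding.nearest_reference[mid][0] for mid in embedding.ids}
    return {
        "models": len(embedding.ids),
        "labels": labels,
        "top_eigenvalues": [round(float(v), 6) for v in embedding.eigenvalues[:3]],
    }
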