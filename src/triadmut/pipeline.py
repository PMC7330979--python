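"""End-to-end pipeline: build database -> search -> graft -> clash -> evaluate.

Stage counts are logged at INFO so a run can be audited: pairs enumerated,
alignments performed after the signature filter, proposals passing the RMSD
gate.  Outputs are TSV tables plus PDB mutants; identical inputs and seeds
give byte-identical tables.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd

from . import signatures
from .config import load_config
from .errors import ConfigError, TriadmutError
from .evaluation import evaluate_proposals
from .search import SearchCounts, SearchParams, propose_mutations, summarize_by_sites, graft_sidechains
from .structure import read_structure, write_structure
from .triads import build_database, save_database, load_database

logger = logging.getLogger(__name__)

PROPOSAL_COLUMNS = ["Mutation", "Template", "Chain", "R1", "R2",
                    "RMSD", "ddG", "Clash", "Categories"]


def proposals_to_frame(proposals) -> pd.DataFrame:
    rows = []
    for p in proposals:
        rows.append({
            "Mutation": p.notation,
            "Template": p.template_source,
            "Chain": p.site_a[0],
            "R1": p.template_pair_names[0],
            "R2": p.template_pair_names[1],
            "RMSD": round(p.rmsd, 4),
            "ddG": "",  # optional external-predictor pass-through, unset here
            "Clash": int(p.clash),
            "Categories": ",".join(sorted(p.categories)),
        })
    return pd.DataFrame(rows, columns=PROPOSAL_COLUMNS)


def run_pipeline(template_paths, target_path, out_dir, chain: str | None = None,
                 config: dict | None = None, config_path=None,
                 region: tuple | None = None, evaluate: bool = True) -> dict:
    """Run every stage on disk inputs; returns paths of the artifacts.

    Any stage failure is re-raised with the stage name prepended.
    """
    cfg = load_config(config_path, config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    def stage(name, fn):
        try:
            return fn()
        except TriadmutError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    db = stage("build-db", lambda: build_database(
        template_paths, cutoff=cfg["cluster_cutoff"], chain=chain))
    logger.info("build-db: %d representatives in %d categories",
                len(db), db.index()["category"].nunique() if len(db) else 0)

    params_sig = signatures.SignatureParams(
        d_min=cfg["sig_d_min"], d_max=cfg["sig_d_max"], step=cfg["sig_step"])
    if len(db):
        stage("signatures", lambda: signatures.fit_database_signatures(
            db, params_sig, cfg["energy_fraction"], cfg["svd_criterion"]))
    db_dir = out_dir / "db"
    stage("save-db", lambda: save_database(db, db_dir))
    artifacts["db"] = db_dir

    target = stage("read-target", lambda: read_structure(target_path, chain=chain))
    sp = SearchParams(
        ca_min=cfg["ca_min"], ca_max=cfg["ca_max"],
        rmsd_threshold=cfg["rmsd_threshold"], clash_cutoff=cfg["clash_cutoff"],
        region_center=region, region_radius=cfg["region_radius"],
        ssv_cutoff=cfg["ssv_cutoff"] if len(db) else math.inf,
        min_seq_separation=cfg["min_seq_separation"])
    counts = SearchCounts()
    proposals = stage("search", lambda: propose_mutations(target, db, sp, counts=counts))
    logger.info("search: %d pairs enumerated, %d alignments after filter, %d proposals",
                counts.pairs_enumerated, counts.alignments_after_filter, counts.proposals)

    frame = proposals_to_frame(proposals)
    frame.to_csv(out_dir / "proposals.tsv", sep="\t", index=False)
    proposals_to_frame(summarize_by_sites(proposals)).to_csv(
        out_dir / "proposals_by_site.tsv", sep="\t", index=False)
    artifacts["proposals"] = out_dir / "proposals.tsv"
    artifacts["proposals_by_site"] = out_dir / "proposals_by_site.tsv"

    if evaluate and proposals:
        mut_dir = out_dir / "mutants"
        mut_dir.mkdir(exist_ok=True)
        mutants, ids = [], []
        for i, p in enumerate(proposals):
            mutant = stage("graft", lambda p=p: graft_sidechains(target, p, db))
            write_structure(mutant, mut_dir / f"mut{i:04d}.pdb")
            mutants.append(mutant)
            ids.append(p.notation)
        table, summary = stage("evaluate", lambda: evaluate_proposals(target, mutants, ids))
        table.to_csv(out_dir / "evaluation.tsv", sep="\t", index=False)
        summary.to_csv(out_dir / "evaluation_summary.tsv", sep="\t", index=False)
        artifacts["evaluation"] = out_dir / "evaluation.tsv"
        artifacts["evaluation_summary"] = out_dir / "evaluation_summary.tsv"
        artifacts["mutants"] = mut_dir
    return artifacts
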