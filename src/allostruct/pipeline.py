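"""End-to-end orchestration of the ensemble analysis behind a YAML config.

Stage order: load -> common frame -> invariant core -> superposition ->
RMSF -> region-wise RMSD -> DCCM -> embeddings (PCA / ICA / LLE) ->
hierarchical clustering & clustroid representatives -> residue interaction
networks (betweenness, center-of-mass distances) -> docking re-score ->
sequence identities.  Stages whose inputs are not configured are marked
skipped; a failing stage halts the run with a stage-named error.  Every
numeric artifact is written in full precision, so a rerun with the same
config and inputs is bytewise reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dccm as dccm_mod
from . import embeddings as emb_mod
from . import ensemble_geometry as geo
from . import rin_networks as rin_mod
from . import screening_rescore as screen_mod
from . import seq_sites
from . import structures_io as sio
from . import synthetic_data as synth

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    structures: list[dict] = field(default_factory=list)   # {path, chain, id}
    synthetic: dict | None = None                            # alternative source
    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            name: (r.start, r.end) for name, r in sio.RAB11_REGIONS.items()
        }
    )
    core: dict = field(default_factory=lambda: {"v_stop": 1.0, "floor": None})
    embedding: dict = field(default_factory=lambda: {
        "pca_d": 3, "ica_d": 2, "lle_d": 2, "lle_k_candidates": [4, 6, 8], "seed": 7,
    })
    clustering: dict = field(default_factory=lambda: {"linkage": "average", "k": 3})
    rin: dict = field(default_factory=lambda: {"cutoff": 7.0})
    sites: dict[str, list[int]] = field(default_factory=lambda: {
        "site1": sorted(screen_mod.SITE1.residues),
        "site2": sorted(screen_mod.SITE2.residues),
    })
    score_table: str | None = None
    sequences: str | None = None            # FASTA path with >= 2 records
    output_dir: str = "allostruct_out"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, val)
        return cfg

    def region_defs(self) -> dict[str, sio.RegionDef]:
        return {n: sio.RegionDef(n, int(a), int(b)) for n, (a, b) in self.regions.items()}


@dataclass
class RunReport:
    stages: dict[str, dict] = field(default_factory=dict)
    headline: dict = field(default_factory=dict)
    manifest: list[str] = field(default_factory=list)

    def record(self, stage: str, status: str, **params):
        self.stages[stage] = {"status": status, **params}

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(
            {"stages": self.stages, "headline": self.headline, "manifest": self.manifest},
            indent=2, default=default, sort_keys=True,
        )


def _load_structures(cfg: PipelineConfig):
    """Returns (structures or None, ensemble_matrix, ground_truth or None)."""
    if cfg.synthetic is not None:
        spec_kind = cfg.synthetic.get("kind", "three_cluster")
        kwargs = {k: v for k, v in cfg.synthetic.items() if k != "kind"}
        if spec_kind == "three_cluster":
            spec = synth.three_cluster_spec(**kwargs)
        elif spec_kind == "single_mode":
            spec = synth.single_mode_spec(**kwargs)
        else:
            raise ValueError(f"unknown synthetic kind {spec_kind!r}")
        ensemble, truth = synth.make_ensemble(spec)
        return None, ensemble, truth
    if not cfg.structures:
        raise ValueError("no structure source configured")
    structures = []
    for entry in cfg.structures:
        with open(entry["path"]) as fh:
            pdb_id = entry.get("id", Path(entry["path"]).stem).rsplit("_", 1)[0]
            structures.append(sio.read_structure(fh.read(), entry["chain"], pdb_id=pdb_id))
    frame = sio.common_residue_frame(structures)
    return structures, geo.ensemble_matrix(structures, frame), None


def _member_structure(ensemble: geo.EnsembleMatrix, i: int) -> sio.Structure:
    """C-alpha-trace Structure for ensemble member i (for network stages)."""
    xyz = ensemble.member_xyz(i)
    residues = [
        sio.Residue(num, "ALA", [sio.Atom("CA", "C", *xyz[j])])
        for j, num in enumerate(ensemble.frame)
    ]
    return sio.Structure(ensemble.ids[i], residues, [])


def run_pipeline(config: PipelineConfig) -> RunReport:
    report = RunReport()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def write_df(df: pd.DataFrame, name: str, **kwargs):
        path = out / name
        df.to_csv(path, **kwargs)
        report.manifest.append(str(path))

    def timed(stage):
        t0 = time.perf_counter()

        def finish(**params):
            report.record(stage, "done", seconds=round(time.perf_counter() - t0, 3), **params)

        return finish

    # ---- load + frame -----------------------------------------------------
    try:
        finish = timed("load")
        structures, ensemble, truth = _load_structures(config)
        finish(n_members=ensemble.n_members, n_residues=ensemble.n_residues)
    except Exception as exc:
        raise StageError("load", exc) from exc

    regions = config.region_defs()

    # ---- invariant core + superposition -----------------------------------
    try:
        finish = timed("superpose")
        core = geo.find_invariant_core(
            ensemble,
            v_stop=float(config.core.get("v_stop", 1.0)),
            floor=config.core.get("floor"),
        )
        aligned = geo.superpose_ensemble(ensemble, core)
        finish(core_size=len(core))
        report.headline["core_size"] = len(core)
    except Exception as exc:
        raise StageError("superpose", exc) from exc

    # ---- RMSF --------------------------------------------------------------
    try:
        finish = timed("rmsf")
        prof = geo.rmsf(aligned)
        write_df(
            pd.DataFrame({"residue": list(aligned.frame), "rmsf": prof}),
            "rmsf.csv", index=False,
        )
        region_means = {}
        for name, reg in regions.items():
            try:
                idx = sio.select_region(aligned.frame, reg)
            except ValueError:
                continue
            region_means[name] = float(prof[idx].mean())
        report.headline["rmsf_region_means"] = region_means
        finish()
    except Exception as exc:
        raise StageError("rmsf", exc) from exc

    # ---- RMSD matrices -----------------------------------------------------
    try:
        finish = timed("rmsd")
        matrices = {"all": geo.pairwise_rmsd(aligned)}
        for name, reg in regions.items():
            try:
                idx = sio.select_region(aligned.frame, reg)
            except ValueError:
                continue
            matrices[name] = geo.pairwise_rmsd(aligned, idx)
        for name, mat in matrices.items():
            write_df(
                pd.DataFrame(mat, index=aligned.ids, columns=aligned.ids),
                f"rmsd_{name}.csv",
            )
        report.headline["rmsd_max"] = {k: float(v.max()) for k, v in matrices.items()}
        finish()
    except Exception as exc:
        raise StageError("rmsd", exc) from exc

    # ---- DCCM --------------------------------------------------------------
    try:
        finish = timed("dccm")
        cmat = dccm_mod.compute_dccm(aligned)
        write_df(
            pd.DataFrame(cmat.matrix, index=list(aligned.frame), columns=list(aligned.frame)),
            "dccm.csv",
        )
        finish(n_rigid=int(cmat.rigid.sum()))
    except Exception as exc:
        raise StageError("dccm", exc) from exc

    # ---- embeddings ---------------------------------------------------------
    try:
        finish = timed("embed")
        ecfg = config.embedding
        d_pca = int(ecfg.get("pca_d", 3))
        emb_pca = emb_mod.pca(aligned, d=d_pca)
        emb_ica = emb_mod.fastica(
            aligned, d=int(ecfg.get("ica_d", 2)), seed=int(ecfg.get("seed", 7))
        )
        k_cands = list(ecfg.get("lle_k_candidates", [4, 6, 8]))
        lle_d = int(ecfg.get("lle_d", 2))
        best_k = emb_mod.select_lle_k(aligned, k_cands, d=lle_d)
        emb_lle = emb_mod.lle(aligned, k=best_k, d=lle_d)
        embeddings = {"pca": emb_pca, "ica": emb_ica, "lle": emb_lle}
        for name, emb in embeddings.items():
            cols = {f"dim{j + 1}": emb.scores[:, j] for j in range(emb.d)}
            write_df(
                pd.DataFrame({"member_id": aligned.ids, **cols}),
                f"embedding_{name}.csv", index=False,
            )
            sidecar = out / f"embedding_{name}.params.json"
            sidecar.write_text(json.dumps(
                {"method": name, **emb.params, "converged": emb.converged}, sort_keys=True
            ))
            report.manifest.append(str(sidecar))
        report.headline["pca_variance_fractions"] = emb_pca.variance_fractions.tolist()
        report.headline["lle_k"] = best_k
        finish(ica_converged=emb_ica.converged)
    except Exception as exc:
        raise StageError("embed", exc) from exc

    # ---- clustering / representatives --------------------------------------
    try:
        finish = timed("cluster")
        k = int(config.clustering.get("k", 3))
        linkage = config.clustering.get("linkage", "average")
        reps: dict[str, list[str]] = {}
        rows = []
        for name, emb in embeddings.items():
            from scipy.spatial.distance import squareform, pdist

            D = squareform(pdist(emb.scores))
            model = geo.hierarchical_cluster(D, k=k, method=linkage, ids=aligned.ids)
            reps[name] = model.clustroids
            for i, member in enumerate(aligned.ids):
                rows.append({
                    "space": name, "member_id": member,
                    "cluster": int(model.labels[i]),
                    "is_clustroid": member in model.clustroids,
                })
        write_df(pd.DataFrame(rows), "clusters.tsv", sep="\t", index=False)
        report.headline["representatives"] = reps
        finish(k=k, linkage=linkage)
    except Exception as exc:
        raise StageError("cluster", exc) from exc

    # ---- residue interaction networks --------------------------------------
    try:
        finish = timed("rin")
        rep_ids = sorted(set(reps["lle"]))
        centr_rows = []
        for rep in rep_ids:
            i = aligned.ids.index(rep)
            st = (
                structures[i] if structures is not None else _member_structure(aligned, i)
            )
            net = rin_mod.build_rin(st, cutoff=float(config.rin.get("cutoff", 7.0)))
            bc = rin_mod.betweenness(net)
            com = rin_mod.center_of_mass_distances(st)
            for node in net.nodes:
                centr_rows.append({
                    "structure": rep, "residue": node,
                    "betweenness": bc[node], "com_distance": com[node],
                })
        write_df(pd.DataFrame(centr_rows), "rin_centrality.csv", index=False)
        finish(n_representatives=len(rep_ids))
    except Exception as exc:
        raise StageError("rin", exc) from exc

    # ---- docking re-score ----------------------------------------------------
    if config.score_table:
        try:
            finish = timed("rescore")
            records = screen_mod.load_scores(config.score_table)
            ranked = screen_mod.weighted_score(records)
            write_df(pd.DataFrame([r.__dict__ for r in ranked]), "rescored.csv", index=False)
            report.headline["top_ligands"] = [r.ligand for r in ranked[:5]]
            finish(n_records=len(ranked))
        except Exception as exc:
            raise StageError("rescore", exc) from exc
    else:
        report.record("rescore", "skipped", reason="no score table configured")

    # ---- sequence identities --------------------------------------------------
    if config.sequences:
        try:
            finish = timed("seqid")
            seqs = sio.read_fasta(config.sequences)
            mat = seq_sites.identity_matrix(seqs)
            write_df(mat, "identity_matrix.csv")
            report.headline["identity_matrix"] = {
                a: {b: float(mat.loc[a, b]) for b in mat.columns} for a in mat.index
            }
            finish(n_sequences=len(seqs))
        except Exception as exc:
            raise StageError("seqid", exc) from exc
    else:
        report.record("seqid", "skipped", reason="no sequences configured")

    if truth is not None and truth.labels is not None:
        report.headline["planted_labels"] = truth.labels.tolist()
        report.headline["planted_core_size"] = len(truth.core_positions)

    report_path = out / "run_report.json"
    report_path.write_text(report.to_json())
    report.manifest.append(str(report_path))
    return report
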