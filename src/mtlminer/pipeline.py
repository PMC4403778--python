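"""End-to-end corpus mining: structure filter, ligand/site extraction,
multi-structure gate, identity filtration, MTL decision, conformer
analysis, chemical annotation, statistics and deterministic export."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import pdb_io, ligand_extract, site_extract, seq_redundancy
from . import conf_analysis, chem_annotate
from .pdb_io import Structure
from .ligand_extract import LigandInstance, instance_filename
from .site_extract import BindingSite
from .seq_redundancy import TargetCluster
from .conf_analysis import ConformerReport
from .chem_annotate import Descriptors, Fingerprint

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every numeric criterion of the mining pipeline."""

    max_resolution: float = 3.0
    require_xray: bool = True
    min_heavy_atoms: int = 8            # strict: kept iff count > this
    site_radius: float = 6.0
    min_site_residues: int = 5          # strict: kept iff residues > this
    identity_threshold: float = 35.0
    identity_filtration: bool = True
    rmsd_class_cutoff: float = 2.0      # inclusive: rigid iff max <= this
    tanimoto_cutoff: float = 0.8
    fingerprint_bits: int = 1024
    fingerprint_max_path: int = 7
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_resolution", "site_radius", "identity_threshold",
                     "rmsd_class_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return cls(**raw)


@dataclass
class LigandRecord:
    """All information mined for one chemical component."""

    component_id: str
    instances: list[LigandInstance]
    sites: list[BindingSite]
    target_clusters: list[TargetCluster]
    nonredundant_target_count: int
    is_mtl: bool
    descriptors: Descriptors | None
    fingerprint: Fingerprint | None
    smiles: str
    conformer_report: ConformerReport | None = None
    primary_chains: list[tuple[tuple[str, str], str]] = field(default_factory=list)
    annotations: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "component_id": self.component_id,
            "instances": [list(i.instance_key) for i in self.instances],
            "sites": [
                {"ligand_ref": list(s.ligand_ref),
                 "residue_count": s.residue_count,
                 "residues": [list(r) for r in s.residues]}
                for s in self.sites
            ],
            "target_clusters": [
                {"members": [list(m) for m in c.members],
                 "representative": list(c.representative)}
                for c in self.target_clusters
            ],
            "nonredundant_target_count": self.nonredundant_target_count,
            "is_mtl": self.is_mtl,
            "descriptors": self.descriptors.to_dict() if self.descriptors else None,
            "fingerprint": self.fingerprint.to_hex() if self.fingerprint else None,
            "smiles": self.smiles,
            "conformer_report": (self.conformer_report.to_dict()
                                 if self.conformer_report else None),
            "annotations": dict(sorted(self.annotations.items())),
        }


@dataclass
class StatsBundle:
    target_count_bins: dict[str, int]
    mw_histogram: dict[str, int]
    rmsd_histogram: dict[str, int]
    druglike_fraction: float
    rigid_fraction: float | None
    annotation_fractions: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "target_count_bins": self.target_count_bins,
            "mw_histogram": self.mw_histogram,
            "rmsd_histogram": self.rmsd_histogram,
            "druglike_fraction": (round(self.druglike_fraction, 6)
                                  if self.druglike_fraction is not None else None),
            "rigid_fraction": (round(self.rigid_fraction, 6)
                               if self.rigid_fraction is not None else None),
            "annotation_fractions": {k: round(v, 6) for k, v in
                                     sorted(self.annotation_fractions.items())},
        }


@dataclass
class MTLDatabase:
    records: dict[str, LigandRecord]
    structure_count: int
    site_count: int
    stats: StatsBundle | None
    config: PipelineConfig
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def mtl_count(self) -> int:
        return sum(1 for r in self.records.values() if r.is_mtl)


def _target_bin(n: int) -> str | None:
    if n == 2:
        return "2"
    if 3 <= n <= 5:
        return "3-5"
    if 6 <= n <= 10:
        return "6-10"
    if n > 10:
        return ">10"
    return None


def compute_stats(db: MTLDatabase) -> StatsBundle:
    """Figure-style statistics: target-count bins over MTL records,
    100-Da MW histogram, 0.5-A max-RMSD histogram with the rigid
    (<= cutoff) fraction, drug-like fraction over all records."""
    bins = {"2": 0, "3-5": 0, "6-10": 0, ">10": 0}
    mw_hist: dict[str, int] = {}
    rmsd_hist: dict[str, int] = {}
    druglike = 0
    evaluable = 0
    rigid = 0
    with_rmsd = 0
    for rec in db.records.values():
        if rec.is_mtl:
            label = _target_bin(rec.nonredundant_target_count)
            if label:
                bins[label] += 1
        if rec.descriptors is not None:
            evaluable += 1
            if rec.descriptors.druglike:
                druglike += 1
            lo = int(rec.descriptors.molecular_weight // 100) * 100
            key = f"{lo}-{lo + 100}"
            mw_hist[key] = mw_hist.get(key, 0) + 1
        report = rec.conformer_report
        if report is not None and report.max_rmsd is not None:
            with_rmsd += 1
            if report.max_rmsd <= db.config.rmsd_class_cutoff:
                rigid += 1
            lo_r = int(report.max_rmsd // 0.5) * 0.5
            key = f"{lo_r:.1f}-{lo_r + 0.5:.1f}"
            rmsd_hist[key] = rmsd_hist.get(key, 0) + 1
    return StatsBundle(
        target_count_bins=bins,
        mw_histogram=dict(sorted(mw_hist.items(),
                                 key=lambda kv: float(kv[0].split("-")[0]))),
        rmsd_histogram=dict(sorted(rmsd_hist.items(),
                                   key=lambda kv: float(kv[0].split("-")[0]))),
        druglike_fraction=(druglike / evaluable) if evaluable else 0.0,
        rigid_fraction=(rigid / with_rmsd) if with_rmsd else None,
    )


def classify_mtl(nonredundant_target_count: int) -> bool:
    """MTL iff the ligand retains >= 2 non-redundant targets."""
    return nonredundant_target_count >= 2


def run_pipeline(pdb_dir: str | Path, config: PipelineConfig | None = None) -> MTLDatabase:
    """Mine a directory of PDB files for multiple-target ligands.

    Stages (in order): structure filter -> ligand extraction -> site
    extraction + site filter -> per-component aggregation -> multi-structure
    gate (>= 2 distinct structures) -> identity filtration -> MTL decision
    -> conformer analysis -> chemical annotation -> statistics. The run is
    deterministic; per-stage counts are recorded in ``stage_counts``.
    """
    config = config or PipelineConfig()
    pdb_dir = Path(pdb_dir)
    files = sorted(p for p in pdb_dir.iterdir()
                   if p.suffix.lower() in (".pdb", ".ent"))
    stage = {
        "files_found": len(files), "parsed": 0, "structures_selected": 0,
        "ligand_instances": 0, "sites_extracted": 0, "sites_kept": 0,
        "components_with_sites": 0, "components_multi_structure": 0,
        "mtl_count": 0,
    }
    structures: list[Structure] = []
    for path in files:
        try:
            s = pdb_io.parse_structure(path.read_text(), structure_id=path.stem)
        except (ValueError, OSError) as exc:
            logger.warning("skipping unreadable file %s: %s", path.name, exc)
            continue
        if not s.structure_id:
            s.structure_id = path.stem
        stage["parsed"] += 1
        if pdb_io.passes_structure_filter(s, config.max_resolution,
                                          config.require_xray):
            structures.append(s)
    stage["structures_selected"] = len(structures)

    # component_id -> list of (instance, site, primary_chain_key, chain_seq)
    per_component: dict[str, list] = {}
    chain_seq_cache: dict[tuple[str, str], str] = {}
    for s in structures:
        sequences = {cs.chain_id: cs.sequence for cs in pdb_io.chain_sequences(s)}
        for cid, seq in sequences.items():
            chain_seq_cache[(s.structure_id, cid)] = seq
        instances = ligand_extract.identify_ligand_instances(
            s, min_heavy_atoms=config.min_heavy_atoms)
        stage["ligand_instances"] += len(instances)
        for lig in instances:
            site = site_extract.extract_binding_site(s, lig,
                                                     radius=config.site_radius)
            stage["sites_extracted"] += 1
            if not site_extract.passes_site_filter(site,
                                                   config.min_site_residues):
                continue
            stage["sites_kept"] += 1
            chain = site_extract.primary_binding_chain(site)
            seq = sequences.get(chain, "")
            if not seq:
                logger.warning("site of %s in %s has no protein sequence",
                               lig.component_id, s.structure_id)
                continue
            per_component.setdefault(lig.component_id, []).append(
                (lig, site, (s.structure_id, chain), seq))
    stage["components_with_sites"] = len(per_component)

    records: dict[str, LigandRecord] = {}
    for comp in sorted(per_component):
        entries = per_component[comp]
        structure_ids = {lig.source_structure_id for lig, _, _, _ in entries}
        if len(structure_ids) < 2:        # multi-structure gate
            continue
        stage["components_multi_structure"] += 1
        chains = [(key, seq) for _, _, key, seq in entries]
        clusters = seq_redundancy.cluster_targets(
            sorted({k: s for k, s in chains}.items()),
            threshold=config.identity_threshold)
        count = seq_redundancy.nonredundant_target_count(
            chains, threshold=config.identity_threshold,
            filtration_enabled=config.identity_filtration)
        is_mtl = classify_mtl(count)
        instances = [lig for lig, _, _, _ in entries]
        sites = [site for _, site, _, _ in entries]
        report = None
        if len(instances) >= 2:
            try:
                report = conf_analysis.conformer_report(
                    instances, class_cutoff=config.rmsd_class_cutoff)
            except ValueError as exc:
                logger.warning("conformer analysis failed for %s: %s", comp, exc)
        descriptors = None
        fingerprint = None
        smiles = ""
        try:
            graph = chem_annotate.graph_from_atoms(instances[0].atoms,
                                                   component_id=comp)
            descriptors = chem_annotate.lipinski(graph)
            fingerprint = chem_annotate.path_fingerprint(
                graph, max_path_len=config.fingerprint_max_path,
                n_bits=config.fingerprint_bits)
            smiles = chem_annotate.to_smiles(graph)
        except ValueError as exc:
            logger.warning("chemical annotation failed for %s: %s", comp, exc)
        records[comp] = LigandRecord(
            component_id=comp, instances=instances, sites=sites,
            target_clusters=clusters, nonredundant_target_count=count,
            is_mtl=is_mtl, descriptors=descriptors, fingerprint=fingerprint,
            smiles=smiles, conformer_report=report, primary_chains=chains,
        )
    stage["mtl_count"] = sum(1 for r in records.values() if r.is_mtl)

    db = MTLDatabase(records=records, structure_count=len(structures),
                     site_count=sum(len(r.sites) for r in records.values()),
                     stats=None, config=config, stage_counts=stage)
    db.stats = compute_stats(db)
    for name, count in stage.items():
        logger.info("stage %s: %d", name, count)
    return db


def annotate_external(db: MTLDatabase,
                      id_lists: dict[str, set[str]]) -> MTLDatabase:
    """Flag records against user-supplied component-ID lists; unknown IDs
    are counted and logged, never fatal."""
    for name, ids in sorted(id_lists.items()):
        unknown = sorted(i for i in ids if i not in db.records)
        if unknown:
            logger.warning("annotation list %r: %d unknown component IDs: %s",
                           name, len(unknown), ",".join(unknown[:10]))
        for comp, rec in db.records.items():
            rec.annotations[name] = comp in ids
        if db.stats is not None:
            n = len(db.records)
            flagged = sum(1 for c in db.records if c in ids)
            db.stats.annotation_fractions[name] = (flagged / n) if n else 0.0
    return db


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def export_database(db: MTLDatabase, out_dir: str | Path) -> dict[str, str]:
    """Write the database tree and return the manifest (path -> sha256).

    Per record: ligand conformer PDBs, site PDBs + residue TSVs, SMILES,
    FASTA of cluster-representative sequences, record JSON. Corpus level:
    config, stage counts, records TSV, fingerprints TSV, clusters TSV,
    stats JSON, manifest.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output path not writable: {out}") from exc

    manifest: dict[str, str] = {}

    def write(relpath: str, text: str) -> None:
        path = out / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        data = text.encode()
        path.write_bytes(data)
        manifest[relpath] = _sha256(data)

    write("config.json", json.dumps(db.config.to_dict(), indent=1,
                                    sort_keys=True) + "\n")
    write("stages.json", json.dumps(db.stage_counts, indent=1,
                                    sort_keys=True) + "\n")
    rec_rows = ["component_id\tn_instances\tn_sites\tnonredundant_targets"
                "\tis_mtl\tmax_rmsd\tdruglike\tsmiles"]
    fp_rows = [f"# n_bits={db.config.fingerprint_bits} "
               f"max_path_len={db.config.fingerprint_max_path} "
               f"hash={chem_annotate.FINGERPRINT_HASH_VERSION}",
               "component_id\tfingerprint_hex"]
    cluster_rows = ["component_id\tchain_key\tcluster_id"]
    for comp in sorted(db.records):
        rec = db.records[comp]
        rec_dir = f"records/{comp}"
        for lig in rec.instances:
            write(f"{rec_dir}/ligand_{instance_filename(lig)}",
                  pdb_io.write_substructure(
                      lig.atoms, header_comment=f"LIGAND {comp}"))
        for site, lig in zip(rec.sites, rec.instances):
            base = instance_filename(lig)[:-4]
            if site.site_atoms:
                write(f"{rec_dir}/site_{base}.pdb",
                      pdb_io.write_substructure(
                          site.site_atoms, header_comment=f"SITE {comp}"))
            write(f"{rec_dir}/site_{base}.tsv",
                  site_extract.site_residues_tsv(site))
        write(f"{rec_dir}/ligand.smi", f"{comp}\t{rec.smiles}\n")
        fasta = []
        seq_by_key = dict(rec.primary_chains)
        for cluster in rec.target_clusters:
            key = cluster.representative
            fasta.append(f">{key[0]}_{key[1]}")
            fasta.append(seq_by_key.get(key, ""))
        write(f"{rec_dir}/targets.fasta", "\n".join(fasta) + "\n")
        write(f"{rec_dir}/record.json",
              json.dumps(rec.to_dict(), indent=1, sort_keys=True) + "\n")
        report = rec.conformer_report
        max_r = ("" if report is None or report.max_rmsd is None
                 else f"{report.max_rmsd:.4f}")
        druglike = "" if rec.descriptors is None else str(rec.descriptors.druglike)
        rec_rows.append(
            f"{comp}\t{len(rec.instances)}\t{len(rec.sites)}\t"
            f"{rec.nonredundant_target_count}\t{rec.is_mtl}\t{max_r}\t"
            f"{druglike}\t{rec.smiles}")
        if rec.fingerprint is not None:
            fp_rows.append(f"{comp}\t{rec.fingerprint.to_hex()}")
        for cid, cluster in enumerate(rec.target_clusters):
            for member in cluster.members:
                cluster_rows.append(f"{comp}\t{'_'.join(member)}\t{cid}")
    write("records.tsv", "\n".join(rec_rows) + "\n")
    write("fingerprints.tsv", "\n".join(fp_rows) + "\n")
    write("clusters.tsv", "\n".join(cluster_rows) + "\n")
    if db.stats is not None:
        write("stats.json", json.dumps(db.stats.to_dict(), indent=1,
                                       sort_keys=True) + "\n")
    manifest_text = json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    (out / "manifest.json").write_bytes(manifest_text.encode())
    return manifest


def load_records(db_dir: str | Path) -> dict[str, dict]:
    """Re-read exported record JSONs (round-trip counterpart of export)."""
    out = Path(db_dir)
    records = {}
    for path in sorted(out.glob("records/*/record.json")):
        raw = json.loads(path.read_text())
        records[raw["component_id"]] = raw
    return records


def load_fingerprints(db_dir: str | Path) -> tuple[dict[str, Fingerprint], dict]:
    """Fingerprints + parameters from an exported fingerprints.tsv."""
    lines = (Path(db_dir) / "fingerprints.tsv").read_text().splitlines()
    params = {}
    for token in lines[0].lstrip("# ").split():
        k, v = token.split("=")
        params[k] = v
    n_bits = int(params["n_bits"])
    fps = {}
    for line in lines[2:]:
        comp, hex_str = line.split("\t")
        fps[comp] = Fingerprint.from_hex(hex_str, n_bits=n_bits)
    return fps, params
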