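"""End-to-end genome-comparison workflow on files, with a manifest.

The pipeline wires the stages together in their natural order: load or
generate a sequence collection; encode the reference copy with structured
identifiers; cross-index the encoded reference back to its source at the
sequence level (fingerprints — masking changes the query stream only, so
reference identities stay recoverable); mask compositional bias in the
query copy; search query vs reference; then cluster the pairs-list into
families two ways (Markov clustering; binary-matrix single linkage with
multi-domain detection) and call gene fusions. Every stage reads files
and writes new files — inputs are never mutated — and the run ends with
a manifest of every artifact and its MD5 checksum, so a rerun with the
same seed is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

from . import align, cast, cogent, diffuse, generage, magicmatch, mcl
from .fixtures import FixtureSpec, make_fixture, write_truth_table
from .io import parse_pairslist, read_fasta, write_fasta, write_pairslist

logger = logging.getLogger(__name__)

CONFIG_VERSION = "1"


@dataclass
class RunConfig:
    """Flat, diff-able run configuration (key=value file; flags override)."""

    config_version: str = CONFIG_VERSION
    seed: int = 17
    # fixture geometry
    n_sequences: int = 30
    length_min: int = 80
    length_max: int = 200
    family_groups: int = 1
    fusion_trios: int = 1
    lcr_implants: int = 1
    lcr_residue: str = "Q"
    lcr_length: int = 20
    # masking
    mask: bool = True
    cast_threshold: int = cast.DEFAULT_THRESHOLD
    # search
    min_score: float = 50.0
    gap_open: int = align.DEFAULT_GAP_OPEN
    gap_extend: int = align.DEFAULT_GAP_EXTEND
    # clustering
    inflation: float = mcl.DEFAULT_INFLATION
    weighting: str = "neglog_evalue"
    # validation
    z_min: float = generage.DEFAULT_Z_MIN
    shuffles: int = generage.DEFAULT_SHUFFLES
    # fusion detection
    max_overlap: float = diffuse.DEFAULT_MAX_OVERLAP
    # identifier encoding of the reference copy
    species_code: str = "Sync"
    assembly_tag: str = "1a"
    version: int = 1


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def validate_config(values: dict | RunConfig) -> RunConfig:
    """Fill defaults, coerce types, reject unknown keys and bad ranges."""
    if isinstance(values, RunConfig):
        values = {f.name: getattr(values, f.name) for f in dc_fields(RunConfig)}
    known = {f.name: f.type for f in dc_fields(RunConfig)}
    defaults = RunConfig()
    out = {}
    for key, raw in values.items():
        if key not in known:
            raise ValueError(f"unknown configuration key {key!r}")
        current = getattr(defaults, key)
        if isinstance(current, bool):
            val = _BOOL.get(str(raw).lower())
            if val is None:
                raise ValueError(f"{key}: expected a boolean, got {raw!r}")
        elif isinstance(current, int):
            val = int(raw)
        elif isinstance(current, float):
            val = float(raw)
        else:
            val = str(raw)
        out[key] = val
    cfg = RunConfig(**out)
    if cfg.config_version != CONFIG_VERSION:
        raise ValueError(f"unsupported config_version {cfg.config_version!r}")
    if cfg.inflation < 1:
        raise ValueError("inflation must be >= 1")
    if cfg.cast_threshold <= 0 or cfg.min_score <= 0:
        raise ValueError("thresholds must be positive")
    if not (0.0 <= cfg.max_overlap <= 1.0):
        raise ValueError("max_overlap must be in [0, 1]")
    if cfg.length_min < 30 or cfg.length_min > cfg.length_max:
        raise ValueError("length range must satisfy 30 <= length_min <= length_max")
    if cfg.seed < 0:
        raise ValueError("seed must be nonnegative")
    return cfg


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` configuration file."""
    values: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key=value")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
    return validate_config(values)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for f in dc_fields(RunConfig):
            fh.write(f"{f.name} = {getattr(cfg, f.name)}\n")


def _md5_file(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full workflow into ``outdir``; returns the manifest path.

    Stage failures abort with the stage name and the offending input in
    the exception message.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[tuple[str, Path]] = []

    def emit(stage: str, path: Path) -> None:
        artifacts.append((stage, path))
        logger.info("[%s] wrote %s", stage, path)

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- fixture -------------------------------------------------------
    def _fixture():
        implants = [
            (i, 11, 10 + cfg.lcr_length, cfg.lcr_residue)
            for i in range(cfg.lcr_implants)
        ]
        spec = FixtureSpec(
            n_sequences=cfg.n_sequences,
            length_range=(cfg.length_min, cfg.length_max),
            seed=cfg.seed,
            lcr_implants=implants,
            fusion_trios=cfg.fusion_trios,
            family_groups=cfg.family_groups,
        )
        records, truth = make_fixture(spec)
        write_fasta(records, outdir / "fixture.faa")
        write_truth_table(truth, outdir / "truth.tsv")
        return records

    records = run_stage("fixture", _fixture)
    emit("fixture", outdir / "fixture.faa")
    emit("fixture", outdir / "truth.tsv")

    # --- reference encoding -------------------------------------------
    def _encode():
        entry = cogent.CatalogEntry(
            str(outdir / "fixture.faa"), cfg.species_code, cfg.assembly_tag, cfg.version
        )
        encoded = cogent.encode_collection(records, entry)
        write_fasta(encoded, outdir / "ref.faa")
        return encoded

    ref_records = run_stage("cogent_encode", _encode)
    emit("cogent_encode", outdir / "ref.faa")

    # --- fingerprint cross-index (reference back to source) ------------
    def _cross():
        table = magicmatch.cross_match(ref_records, records)
        magicmatch.write_cross(table, outdir / "cross.tsv")
        return table

    run_stage("magicmatch", _cross)
    emit("magicmatch", outdir / "cross.tsv")

    # --- query masking -------------------------------------------------
    def _mask():
        masked = []
        regions_map = {}
        for rec in ref_records:
            if cfg.mask:
                regions = cast.detect(rec, threshold=cfg.cast_threshold)
            else:
                regions = []
            regions_map[rec.id] = regions
            masked.append(cast.mask(rec, regions))
        write_fasta(masked, outdir / "query_masked.faa")
        cast.write_regions(regions_map, outdir / "regions.tsv")
        return masked

    query_records = run_stage("cast_mask", _mask)
    emit("cast_mask", outdir / "query_masked.faa")
    emit("cast_mask", outdir / "regions.tsv")

    # --- search ---------------------------------------------------------
    def _search():
        edges = align.search(
            query_records,
            ref_records,
            gap_open=cfg.gap_open,
            gap_extend=cfg.gap_extend,
            min_score=cfg.min_score,
        )
        write_pairslist(edges, outdir / "pairs.tsv", comments=[align.SEARCH_COMMENT])
        return edges

    run_stage("search", _search)
    emit("search", outdir / "pairs.tsv")
    edges = parse_pairslist(outdir / "pairs.tsv", dialect="blast12_commented")

    # --- Markov clustering ---------------------------------------------
    def _clustt():
        graph = mcl.build_graph(edges, weighting=cfg.weighting)
        fams = mcl.mcl(graph, inflation=cfg.inflation)
        return mcl.emit_outputs(graph, fams, outdir / "clustt")

    for path in run_stage("clustt_mcl", _clustt):
        emit("clustt_mcl", path)

    # --- binary-matrix clustering + multi-domain ------------------------
    def _generage():
        ids = [r.id for r in ref_records]
        m = generage.build_matrix(edges, ids)
        m = generage.symmetrify(
            m,
            ref_records,
            z_min=cfg.z_min,
            n_shuffles=cfg.shuffles,
            seed=cfg.seed,
        )
        calls = generage.detect_multidomain(m)
        fams = generage.cluster(m, calls)
        generage.write_families(fams, outdir / "generage.families.tsv")
        generage.write_multidomain(calls, outdir / "generage.multidomain.tsv")

    run_stage("generage", _generage)
    emit("generage", outdir / "generage.families.tsv")
    emit("generage", outdir / "generage.multidomain.tsv")

    # --- gene-fusion detection ------------------------------------------
    def _diffuse():
        rect = diffuse.build_rect_matrix(
            records,
            ref_records,
            min_score=cfg.min_score,
            gap_open=cfg.gap_open,
            gap_extend=cfg.gap_extend,
        )
        cands = diffuse.detect_fusions(
            rect,
            records,
            max_component_overlap=cfg.max_overlap,
            z_min=cfg.z_min,
            n_shuffles=cfg.shuffles,
            seed=cfg.seed,
        )
        diffuse.write_fusions(cands, outdir / "fusions.tsv")

    run_stage("diffuse", _diffuse)
    emit("diffuse", outdir / "fusions.tsv")

    write_config(cfg, outdir / "run.cfg")
    emit("config", outdir / "run.cfg")

    manifest_path = outdir / "manifest.tsv"
    with open(manifest_path, "wt") as fh:
        for stage, path in artifacts:
            fh.write(
                f"{stage}\t{path.name}\t{_md5_file(path)}\t{path.stat().st_size}\n"
            )
    return manifest_path
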