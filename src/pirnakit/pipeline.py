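"""End-to-end pipeline: preprocess, annotate, metrics, ping-pong.

The pipeline is driven by a flat key-value config file (YAML mapping of
scalars). Library entries use prefixed keys (``library.<name>.fastq``,
``library.<name>.kind``), catalog entries likewise (``catalog.<category>``),
so the document stays flat while supporting any number of libraries.
Unknown keys are rejected — silent typos are the main reproducibility
hazard — and validation reports every violation at once.

Per-library normalization follows library kind: total-RNA libraries are
normalized by miRNA counts, IP libraries by total (clipped) reads; either
can be overridden per library.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import SeedIndex, align_library
from .annotate import annotate_library, annotation_composition
from .catalog import CANONICAL_ORDER, ReferenceCatalog
from .errors import ConfigurationError, DataError
from .metrics import (
    cluster_counts,
    compare_spectra,
    first_nt_composition,
    length_spectrum,
    mirna_count,
)
from .pingpong import (
    collect_five_primes,
    pingpong_profile,
    pingpong_zscore,
    strand_coverage,
)
from .preprocess import PreprocessParams, preprocess_library, read_fastq, \
    write_collapsed_fasta, counts_table

logger = logging.getLogger("pirnakit")

LIBRARY_KINDS = ("total", "mili_ip", "miwi_ip")
_KIND_DEFAULT_NORMALIZER = {
    "total": "mirna_counts",
    "mili_ip": "total_reads",
    "miwi_ip": "total_reads",
}

# key -> (type, default); None default means required
_SCALAR_KEYS = {
    "seed": (int, 1),
    "output_dir": (str, None),
    "adapter": (str, None),
    "min_overlap": (int, 5),
    "max_adapter_mismatch_rate": (float, 0.1),
    "keep_unclipped": (bool, False),
    "len_min": (int, 24),
    "len_max": (int, 32),
    "max_mm": (int, 1),
    "pingpong_k": (int, 20),
    "top_n": (int, 50),
    "catalog_order": (str, ",".join(CANONICAL_ORDER)),
    "element_fasta": (str, ""),
    "element_name": (str, ""),
    "run_pingpong": (bool, None),  # default: element_fasta given
    "control_library": (str, ""),
    "pair_weighting": (str, "abundance"),
}


@dataclass
class LibraryConfig:
    name: str
    fastq: str
    kind: str
    normalizer_kind: str


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    adapter: str
    min_overlap: int
    max_adapter_mismatch_rate: float
    keep_unclipped: bool
    len_min: int
    len_max: int
    max_mm: int
    pingpong_k: int
    top_n: int
    catalog_paths: list  # ordered (category, path)
    element_fasta: str
    element_name: str
    run_pingpong: bool
    control_library: str
    pair_weighting: str
    libraries: list = field(default_factory=list)

    def preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(
            adapter=self.adapter,
            min_overlap=self.min_overlap,
            max_adapter_mismatch_rate=self.max_adapter_mismatch_rate,
            keep_unclipped=self.keep_unclipped,
            len_min=self.len_min,
            len_max=self.len_max,
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "adapter": self.adapter,
            "min_overlap": self.min_overlap,
            "max_adapter_mismatch_rate": self.max_adapter_mismatch_rate,
            "keep_unclipped": self.keep_unclipped,
            "len_min": self.len_min,
            "len_max": self.len_max,
            "max_mm": self.max_mm,
            "pingpong_k": self.pingpong_k,
            "top_n": self.top_n,
            "catalog": [[c, str(p)] for c, p in self.catalog_paths],
            "element_fasta": self.element_fasta,
            "element_name": self.element_name,
            "run_pingpong": self.run_pingpong,
            "control_library": self.control_library,
            "pair_weighting": self.pair_weighting,
            "libraries": [
                [l.name, l.fastq, l.kind, l.normalizer_kind]
                for l in self.libraries
            ],
        }


def _coerce(key, value, typ, errors):
    if typ is bool:
        if isinstance(value, bool):
            return value
        errors.append(f"{key}: expected a boolean, got {value!r}")
        return None
    if typ is int:
        if isinstance(value, bool) or not isinstance(value, int):
            errors.append(f"{key}: expected an integer, got {value!r}")
            return None
        return value
    if typ is float:
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return float(value)
        errors.append(f"{key}: expected a number, got {value!r}")
        return None
    return str(value)


def validate_config(path) -> PipelineConfig:
    """Parse and validate a flat pipeline config file.

    Applies defaults, checks types, file existence and cross-field
    consistency, and raises a single ConfigurationError carrying every
    violation found (never just the first).
    """
    path = Path(path)
    errors: list[str] = []
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigurationError([f"cannot parse config {path}: {exc}"])
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(
            [f"config {path} must be a flat key-value mapping"]
        )

    scalars = {}
    lib_entries: dict[str, dict] = {}
    catalog_entries: dict[str, str] = {}
    for key, value in raw.items():
        if key in _SCALAR_KEYS:
            typ, _ = _SCALAR_KEYS[key]
            coerced = _coerce(key, value, typ, errors)
            if coerced is not None:
                scalars[key] = coerced
        elif key.startswith("library."):
            parts = key.split(".")
            if len(parts) != 3 or parts[2] not in ("fastq", "kind", "normalizer"):
                errors.append(f"unknown library key {key!r}")
                continue
            lib_entries.setdefault(parts[1], {})[parts[2]] = str(value)
        elif key.startswith("catalog."):
            cat = key.split(".", 1)[1]
            catalog_entries[cat] = str(value)
        else:
            errors.append(f"unknown config key {key!r}")

    values = {}
    for key, (typ, default) in _SCALAR_KEYS.items():
        if key in scalars:
            values[key] = scalars[key]
        elif default is None and key != "run_pingpong":
            errors.append(f"missing required key {key!r}")
        else:
            values[key] = default

    if values.get("run_pingpong") is None:
        values["run_pingpong"] = bool(values.get("element_fasta"))

    # window / parameter sanity
    if "len_min" in values and "len_max" in values:
        if not 0 < values["len_min"] <= values["len_max"]:
            errors.append("length window requires 0 < len_min <= len_max")
    if values.get("max_mm") not in (0, 1, None):
        errors.append("max_mm must be 0 or 1")
    if values.get("pingpong_k", 1) < 1:
        errors.append("pingpong_k must be >= 1")
    if values.get("top_n", 1) < 1:
        errors.append("top_n must be >= 1")
    if values.get("pair_weighting") not in ("abundance", "unique", None):
        errors.append("pair_weighting must be 'abundance' or 'unique'")

    # catalog
    order = [c for c in values.get("catalog_order", "").split(",") if c]
    catalog_paths = []
    for cat in order:
        if cat not in catalog_entries:
            errors.append(f"catalog_order names {cat!r} but catalog.{cat} is missing")
        else:
            catalog_paths.append((cat, catalog_entries.pop(cat)))
    for cat in catalog_entries:
        errors.append(f"catalog.{cat} is not listed in catalog_order")
    if not catalog_paths and not errors:
        errors.append("no catalog categories configured")
    for cat, p in catalog_paths:
        if not Path(p).is_file():
            errors.append(f"catalog.{cat}: file not found: {p}")

    # element
    if values.get("run_pingpong") and not values.get("element_fasta"):
        errors.append("run_pingpong requested but element_fasta is not set")
    if values.get("element_fasta") and not Path(values["element_fasta"]).is_file():
        errors.append(f"element_fasta: file not found: {values['element_fasta']}")

    # libraries
    libraries = []
    for name in sorted(lib_entries):
        entry = lib_entries[name]
        fastq = entry.get("fastq")
        kind = entry.get("kind", "total")
        if fastq is None:
            errors.append(f"library.{name}.fastq is missing")
            continue
        if not Path(fastq).is_file():
            errors.append(f"library.{name}.fastq: file not found: {fastq}")
        if kind not in LIBRARY_KINDS:
            errors.append(
                f"library.{name}.kind must be one of {LIBRARY_KINDS}, got {kind!r}"
            )
            continue
        normalizer = entry.get("normalizer", _KIND_DEFAULT_NORMALIZER[kind])
        if normalizer not in ("mirna_counts", "total_reads"):
            errors.append(
                f"library.{name}.normalizer must be 'mirna_counts' or "
                f"'total_reads', got {normalizer!r}"
            )
            continue
        libraries.append(LibraryConfig(name, fastq, kind, normalizer))
    if not libraries and not lib_entries:
        errors.append("no libraries configured (library.<name>.fastq keys)")

    control = values.get("control_library") or (
        libraries[0].name if libraries else ""
    )
    if libraries and control not in {l.name for l in libraries}:
        errors.append(f"control_library {control!r} is not a configured library")

    if errors:
        raise ConfigurationError(errors)

    return PipelineConfig(
        seed=values["seed"],
        output_dir=values["output_dir"],
        adapter=values["adapter"],
        min_overlap=values["min_overlap"],
        max_adapter_mismatch_rate=values["max_adapter_mismatch_rate"],
        keep_unclipped=values["keep_unclipped"],
        len_min=values["len_min"],
        len_max=values["len_max"],
        max_mm=values["max_mm"],
        pingpong_k=values["pingpong_k"],
        top_n=values["top_n"],
        catalog_paths=catalog_paths,
        element_fasta=values["element_fasta"],
        element_name=values["element_name"],
        run_pingpong=values["run_pingpong"],
        control_library=control,
        pair_weighting=values["pair_weighting"],
        libraries=libraries,
    )


def _write_tsv(frame: pd.DataFrame, path) -> None:
    # fixed float format keeps reruns byte-identical
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage for every configured library.

    Writes per-library TSV reports, cross-library ratio tables against the
    control library, and a run manifest; returns a report dict with the
    headline numbers. Deterministic: identical config and inputs give
    byte-identical outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    catalog = ReferenceCatalog.from_fasta(config.catalog_paths)
    index = SeedIndex(catalog)

    element_name = None
    element_index = None
    element_len = 0
    if config.run_pingpong:
        from Bio import SeqIO

        records = list(SeqIO.parse(config.element_fasta, "fasta"))
        if not records:
            raise DataError(f"element_fasta {config.element_fasta} is empty")
        wanted = config.element_name or records[0].id
        by_id = {rec.id: str(rec.seq).upper() for rec in records}
        if wanted not in by_id:
            raise DataError(
                f"element_name {wanted!r} not present in {config.element_fasta}"
            )
        element_name = wanted
        element_seq = by_id[wanted]
        element_len = len(element_seq)
        element_index = SeedIndex(
            ReferenceCatalog([("element", {element_name: element_seq})])
        )

    params = config.preprocess_params()
    report: dict = {"libraries": {}}
    spectra = {}

    for lib in config.libraries:
        logger.info("processing library %s (%s)", lib.name, lib.kind)
        libdir = outdir / lib.name
        libdir.mkdir(parents=True, exist_ok=True)

        reads = read_fastq(lib.fastq)
        pre = preprocess_library(reads, params)
        n_mirna = mirna_count(pre.clipped)
        n_total = len(pre.clipped)
        if lib.normalizer_kind == "mirna_counts":
            normalizer = n_mirna
        else:
            normalizer = n_total
        if normalizer <= 0:
            raise DataError(
                f"library {lib.name}: normalizer {lib.normalizer_kind} is zero"
            )

        write_collapsed_fasta(pre.collapsed, libdir / "collapsed.fasta")
        _write_tsv(counts_table(pre.collapsed), libdir / "collapsed_counts.tsv")
        stats = dict(pre.stats)
        stats["mirna_count"] = n_mirna
        stats["normalizer_kind"] = lib.normalizer_kind
        stats["normalizer_value"] = normalizer
        _write_tsv(
            pd.DataFrame([stats]), libdir / "preprocess_stats.tsv"
        )

        annotated = annotate_library(pre.collapsed, index, config.max_mm)
        composition = annotation_composition(
            annotated, categories=catalog.category_names
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "category": list(composition.keys()),
                    "fraction": list(composition.values()),
                }
            ),
            libdir / "annotation_composition.tsv",
        )

        spectrum = length_spectrum(
            pre.collapsed, lib.normalizer_kind, normalizer
        )
        spectra[lib.name] = spectrum
        _write_tsv(spectrum.to_frame(), libdir / "length_spectrum.tsv")

        firstnt = first_nt_composition(pre.collapsed)
        _write_tsv(
            pd.DataFrame(
                {"base": list(firstnt.keys()), "fraction": list(firstnt.values())}
            ),
            libdir / "first_nt.tsv",
        )

        clusters = cluster_counts(
            annotated,
            top_n=config.top_n,
            normalizer_kind=lib.normalizer_kind,
            normalizer_value=normalizer,
            catalog=catalog,
        )
        _write_tsv(clusters, libdir / "cluster_counts.tsv")

        lib_report = {
            "stats": stats,
            "composition": composition,
            "first_nt": firstnt,
            "outputs": str(libdir),
        }

        if config.run_pingpong:
            pairs = align_library(pre.collapsed, element_index, config.max_mm)
            fives = collect_five_primes(
                pairs, element_name, weighting=config.pair_weighting
            )
            profile = pingpong_profile(fives, config.pingpong_k)
            _write_tsv(profile.to_frame(), libdir / "pingpong_profile.tsv")
            coverage = strand_coverage(
                fives, element_len, lib.normalizer_kind, normalizer
            )
            _write_tsv(coverage.to_frame(), libdir / "strand_coverage.tsv")
            zscore = pingpong_zscore(profile) if config.pingpong_k >= 5 else None
            lib_report["pingpong_total_pair_weight"] = profile.total_pair_weight
            lib_report["pingpong_zscore_10"] = zscore

        report["libraries"][lib.name] = lib_report

    # cross-library ratio tables against the control, same normalizer kind
    control = config.control_library
    for lib in config.libraries:
        if lib.name == control:
            continue
        ctrl_spec = spectra[control]
        lib_spec = spectra[lib.name]
        if ctrl_spec.normalizer_kind != lib_spec.normalizer_kind:
            logger.info(
                "skipping ratio %s vs %s: different normalizer kinds",
                lib.name, control,
            )
            continue
        ratios = compare_spectra(ctrl_spec, lib_spec)
        _write_tsv(ratios, outdir / f"ratio_{lib.name}_vs_{control}.tsv")

    # long-format spectra for plotting
    long_rows = []
    for name, spec in spectra.items():
        for length, abundance in sorted(spec.normalized.items()):
            long_rows.append(
                {"library": name, "length": length, "abundance": abundance}
            )
    _write_tsv(pd.DataFrame(long_rows), outdir / "spectra_long.tsv")

    manifest = {
        "config": config.to_dict(),
        "versions": {
            "pirnakit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    report["manifest"] = str(outdir / "manifest.json")
    return report
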