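"""File I/O: read sets, locus configs, reports, histograms and the bundled cohort.

FASTA and FASTQ are both accepted (base qualities are never used by the
pipeline — all filters are identity-based); gzip compression is handled
transparently by file extension.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import ConfigurationError, InputError
from .genotype import ReadCall
from .locus import Flank2Layout, LocusSpec
from .report import (
    AlleleSummary,
    PhaseDecision,
    SampleReport,
    classify_sample,
    control_locus_call,
    phase_method_from_genotypes,
)

_FORMATS = {
    ".fa": "fasta", ".fasta": "fasta", ".fna": "fasta",
    ".fq": "fastq", ".fastq": "fastq",
}


def read_fastx(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA/FASTQ, optionally gzipped."""
    path = Path(path)
    suffixes = path.suffixes
    opener = open
    fmt_suffix = suffixes[-1] if suffixes else ""
    if fmt_suffix == ".gz":
        opener = gzip.open  # type: ignore[assignment]
        fmt_suffix = suffixes[-2] if len(suffixes) > 1 else ""
    fmt = _FORMATS.get(fmt_suffix)
    if fmt is None:
        raise InputError(f"unrecognized read-file extension on {path.name}")
    try:
        with opener(path, "rt") as fh:
            records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    except ValueError as exc:
        raise InputError(f"malformed {fmt.upper()} in {path}: {exc}") from exc
    if not records:
        raise InputError(f"no reads found in {path}")
    return records


def read_locus_config(path) -> list[LocusSpec]:
    """Load one or more locus definitions from a YAML config file.

    Top-level key ``loci`` is a list of mappings with keys: name, repeat_unit,
    flank1, expansion_threshold, optional control_threshold and thresholds,
    and either ``flank2`` (a constant sequence) or ``flank2_layout`` (mapping
    with spacer, spacer_to_snp, snp_alleles, rest, and optional tract
    parameters).
    """
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except OSError as exc:
        raise InputError(f"cannot read locus config {path}: {exc}") from exc
    if not isinstance(data, dict) or "loci" not in data:
        raise ConfigurationError(f"locus config {path} lacks a top-level 'loci' list")
    loci = []
    for entry in data["loci"]:
        try:
            layout = None
            if "flank2_layout" in entry:
                ld = dict(entry["flank2_layout"])
                ld["snp_alleles"] = tuple(ld["snp_alleles"])
                layout = Flank2Layout(**ld)
            loci.append(
                LocusSpec(
                    name=entry["name"],
                    repeat_unit=entry["repeat_unit"],
                    flank1=entry["flank1"],
                    flank2_layout=layout,
                    flank2_const=entry.get("flank2"),
                    expansion_threshold=entry.get("expansion_threshold", 50),
                    control_threshold=entry.get("control_threshold"),
                    min_flank_identity=entry.get("min_flank_identity", 0.90),
                    min_template_similarity=entry.get("min_template_similarity", 0.99),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(
                f"invalid locus entry in {path}: {exc}"
            ) from exc
    return loci


def write_templates_fasta(pool, path) -> None:
    """Export a template pool as multi-FASTA with canonical IDs."""
    with open(path, "w") as fh:
        for tpl in pool:
            fh.write(f">{tpl.template_id}\n{tpl.sequence}\n")


# ---------------------------------------------------------------------------
# sample reports

def report_to_dict(report: SampleReport) -> dict:
    return asdict(report)


def write_report_json(report: SampleReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report_json(path) -> SampleReport:
    with open(path) as fh:
        data = json.load(fh)
    try:
        phase = data["phase"]
        keys = phase.get("allele_keys")
        if keys is not None:
            keys = tuple(tuple(k) for k in keys)
        return SampleReport(
            sample_id=data["sample_id"],
            phase=PhaseDecision(method=phase["method"], allele_keys=keys),
            alleles=[AlleleSummary(**a) for a in data["alleles"]],
            category=data["category"],
            on_target_counts=data["on_target_counts"],
            control_calls=data.get("control_calls", {}),
            interruptions=[],
        )
    except (KeyError, TypeError) as exc:
        raise InputError(f"malformed sample report {path}: {exc}") from exc


def write_read_calls_tsv(calls: list[ReadCall], path) -> None:
    rows = [
        {
            "read_id": c.read_id,
            "repeat_len": c.repeat_len,
            "similarity": round(c.similarity, 6),
            "edits": c.edits,
            "template_id": c.template_id,
            "sec_tract_len": c.markers.sec_tract_len,
            "snp_allele": c.markers.snp_allele,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "read_id", "repeat_len", "similarity", "edits",
            "template_id", "sec_tract_len", "snp_allele",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_histogram_tsv(lengths: list[int], path) -> None:
    """Read count per repeat length (the tested histogram surface)."""
    if lengths:
        series = pd.Series(lengths).value_counts().sort_index()
        df = pd.DataFrame({"repeat_len": series.index, "n_reads": series.values})
    else:
        df = pd.DataFrame(columns=["repeat_len", "n_reads"])
    df.to_csv(path, sep="\t", index=False)


def plot_histogram(lengths_by_group: dict[str, list[int]], path, title="") -> None:
    """Cosmetic histogram image (read count vs repeat length per allele)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    for label, lengths in lengths_by_group.items():
        if lengths:
            ax.hist(lengths, bins=range(min(lengths), max(lengths) + 2),
                    alpha=0.6, label=label)
    ax.set_xlabel("repeat length (units)")
    ax.set_ylabel("read count")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# bundled cohort fixture

@dataclass
class FixtureAllele:
    phased_reads: Optional[int]
    mode: Optional[int]
    ctc: Optional[int]
    mean: Optional[int]
    size_range: Optional[int]
    max: Optional[int]
    str_genotype: str
    fmr1_cgg: Optional[int]

    @property
    def str_value(self) -> int:
        """Numeric STR repeat count ('>=N' lower bounds read as N)."""
        s = self.str_genotype.lstrip(">=")
        return int(s)


@dataclass
class FixtureSample:
    sample_id: str
    category: str
    on_target_tcf4: int
    on_target_fmr1: int
    phase_method: str
    snp_genotype: tuple[str, str]
    alleles: list[FixtureAllele]


_PHASE_LABELS = {
    "None": "none",
    "SNP": "SNP",
    "CTC": "CTC",
    "CTC length and SNP": "CTC_and_SNP",
}


def load_cohort_fixture() -> list[FixtureSample]:
    """The bundled 11-sample FECD cohort summary table."""
    text = resources.files("noamp").joinpath("data/fecd_cohort.json").read_text()
    data = json.loads(text)
    samples = []
    for s in data["samples"]:
        alleles = [
            FixtureAllele(
                phased_reads=a["phased_reads"],
                mode=None if a["mode"] is None else int(a["mode"]),
                ctc=a["ctc"],
                mean=a["mean"],
                size_range=a["size_range"],
                max=a["max"],
                str_genotype=str(a["str_genotype"]),
                fmr1_cgg=a["fmr1_cgg"],
            )
            for a in s["alleles"]
        ]
        samples.append(
            FixtureSample(
                sample_id=str(s["sample_id"]),
                category=s["category"],
                on_target_tcf4=s["on_target_tcf4"],
                on_target_fmr1=s["on_target_fmr1"],
                phase_method=s["phase_method"],
                snp_genotype=tuple(s["snp_genotype"].split("/")),
                alleles=alleles,
            )
        )
    return samples


def fixture_to_reports(
    samples: list[FixtureSample],
    expansion_threshold: int = 50,
    control_threshold: int = 55,
) -> list[SampleReport]:
    """Recompute SampleReports from the fixture's printed marker genotypes.

    Phase methods, categories and control-locus flags are *derived* from the
    stored genotypes (heterozygosity rule, expansion thresholds), not copied
    from the table's own labels, so summary operations exercise the actual
    classification code.
    """
    reports = []
    for s in samples:
        method = phase_method_from_genotypes(
            s.snp_genotype, (s.alleles[0].ctc, s.alleles[1].ctc)
        )
        alleles = []
        for a in s.alleles:
            alleles.append(
                AlleleSummary(
                    n_reads=a.phased_reads or 0,
                    mode_len=a.mode,
                    mean_len=a.mean,
                    min_len=None if a.max is None or a.size_range is None
                    else a.max - a.size_range,
                    max_len=a.max,
                    size_range=a.size_range,
                    expanded=None if a.mode is None
                    else a.mode >= expansion_threshold,
                    sec_tract_len=a.ctc,
                )
            )
        modes = (s.alleles[0].str_value, s.alleles[1].str_value)
        cgg = tuple(a.fmr1_cgg for a in s.alleles if a.fmr1_cgg is not None)
        if len(cgg) == 1:
            cgg = (cgg[0], cgg[0])
        reports.append(
            SampleReport(
                sample_id=s.sample_id,
                phase=PhaseDecision(method=method),
                alleles=alleles,
                category=classify_sample(modes, expansion_threshold),
                on_target_counts={
                    "TCF4": s.on_target_tcf4,
                    "FMR1": s.on_target_fmr1,
                },
                control_calls={
                    "FMR1": {
                        "modes": list(cgg[:2]),
                        "expanded": list(
                            control_locus_call(cgg[:2], control_threshold)
                        ),
                    }
                },
            )
        )
    return reports
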