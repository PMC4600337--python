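"""Readers and writers for the text formats the pipeline consumes and emits.

Genotypes travel as PLINK-dialect text PED/MAP (one sample per PED row,
genotypes as allele pairs, ``0 0`` missing; MAP columns chromosome, marker
id, genetic distance placeholder, bp position).  Because PED carries no
allele orientation, an optional allele sidecar (marker_id, ref, alt) pins
the alt allele; without it the minor allele is taken as alternative.
Phenotype labels live in a two-column sidecar.  Pileup summaries are a
documented TSV; variant calls are written as VCF v4.2; shared regions as a
tab-separated table with 1-based inclusive coordinates.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import (
    CASE,
    CONTROL,
    MISSING,
    OBLIGATE_CARRIER,
    GenotypeMatrix,
    MarkerRecord,
    PileupSite,
)
from .roh import SharedRegion
from .variants import NOCALL, RULE_NAMES, VariantCall

PathLike = Union[str, Path]

# PLINK phenotype column codes
_PED_PHENO = {CASE: "2", CONTROL: "1", OBLIGATE_CARRIER: "0"}
_PED_PHENO_BACK = {"2": CASE, "1": CONTROL, "0": OBLIGATE_CARRIER, "-9": CONTROL}


# -- PED/MAP ------------------------------------------------------------------

def write_ped_map(gm: GenotypeMatrix, prefix: PathLike) -> Dict[str, Path]:
    """Write ``<prefix>.ped/.map`` plus allele and phenotype sidecars.

    Returns the paths written.  Coordinates are 1-based; genotype code 2
    means two copies of the marker's alternative allele.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": prefix.with_suffix(".ped"),
        "map": prefix.with_suffix(".map"),
        "alleles": prefix.with_suffix(".alleles.tsv"),
        "phenotypes": prefix.with_suffix(".phen.tsv"),
    }
    with open(paths["map"], "w") as fh:
        for m in gm.markers:
            fh.write(f"{m.chromosome}\t{m.marker_id}\t0\t{m.position_bp}\n")
    with open(paths["ped"], "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = [sid, sid, "0", "0", "0", _PED_PHENO[gm.phenotypes[sid]]]
            for j, m in enumerate(gm.markers):
                g = gm.genotypes[i, j]
                ref, alt = m.alleles
                pair = {
                    0: (ref, ref),
                    1: (ref, alt),
                    2: (alt, alt),
                    MISSING: ("0", "0"),
                }[int(g)]
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")
    with open(paths["alleles"], "w") as fh:
        fh.write("marker_id\tref\talt\n")
        for m in gm.markers:
            fh.write(f"{m.marker_id}\t{m.alleles[0]}\t{m.alleles[1]}\n")
    with open(paths["phenotypes"], "w") as fh:
        fh.write("sample_id\tphenotype\n")
        for sid in gm.sample_ids:
            fh.write(f"{sid}\t{gm.phenotypes[sid]}\n")
    return paths


def read_ped_map(
    ped_path: PathLike,
    map_path: PathLike,
    alleles_path: Optional[PathLike] = None,
    phenotypes_path: Optional[PathLike] = None,
) -> GenotypeMatrix:
    """Read PLINK-dialect text PED/MAP into a :class:`GenotypeMatrix`.

    Alleles are recoded to {0,1,2,missing} with the alternative allele
    taken from the allele sidecar when given, otherwise the minor allele.
    ``0 0`` is missing.  Raises with the offending line number on
    malformed input; MAP files must be position-sorted within chromosome.
    """
    markers_raw: List[Tuple[str, str, int]] = []
    with open(map_path) as fh:
        prev: Optional[Tuple[str, int]] = None
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}")
            chrom, mid, _, pos = parts
            try:
                pos_i = int(pos)
            except ValueError:
                raise ValueError(f"{map_path}:{lineno}: bad position {pos!r}") from None
            if prev is not None and prev[0] == chrom and pos_i <= prev[1]:
                raise ValueError(
                    f"{map_path}:{lineno}: markers must be position-sorted within "
                    f"chromosome (got {pos_i} after {prev[1]})"
                )
            prev = (chrom, pos_i)
            markers_raw.append((chrom, mid, pos_i))
    n_markers = len(markers_raw)

    sample_ids: List[str] = []
    ped_pheno: Dict[str, str] = {}
    allele_rows: List[List[Tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} fields "
                    f"({n_markers} markers), got {len(parts)}"
                )
            sid = parts[1]
            sample_ids.append(sid)
            ped_pheno[sid] = _PED_PHENO_BACK.get(parts[5], CONTROL)
            pairs = []
            for j in range(n_markers):
                a, b = parts[6 + 2 * j], parts[7 + 2 * j]
                if (a == "0") != (b == "0"):
                    raise ValueError(
                        f"{ped_path}:{lineno}: half-missing genotype {a!r} {b!r} "
                        f"at marker {j + 1}"
                    )
                pairs.append((a, b))
            allele_rows.append(pairs)

    orientation: Dict[str, Tuple[str, str]] = {}
    if alleles_path is not None:
        tbl = pd.read_csv(alleles_path, sep="\t", dtype=str)
        orientation = {
            r.marker_id: (r.ref, r.alt) for r in tbl.itertuples(index=False)
        }

    genotypes = np.full((len(sample_ids), n_markers), MISSING, dtype=np.int8)
    markers: List[MarkerRecord] = []
    for j, (chrom, mid, pos) in enumerate(markers_raw):
        observed = [p for row in allele_rows for p in (row[j][0], row[j][1]) if p != "0"]
        if mid in orientation:
            ref, alt = orientation[mid]
        else:
            uniq, counts = np.unique(observed, return_counts=True) if observed else ([], [])
            if len(uniq) > 2:
                raise ValueError(f"marker {mid}: more than two alleles {list(uniq)}")
            if len(uniq) == 0:
                ref, alt = "A", "B"  # all-missing marker; arbitrary labels
            elif len(uniq) == 1:
                ref, alt = str(uniq[0]), "B" if uniq[0] != "B" else "A"
            else:
                order = np.argsort(counts)  # minor allele = alternative
                alt, ref = str(uniq[order[0]]), str(uniq[order[1]])
        markers.append(MarkerRecord(mid, chrom, pos, (ref, alt)))
        for i, row in enumerate(allele_rows):
            a, b = row[j]
            if a == "0":
                continue
            code = 0
            for x in (a, b):
                if x == alt:
                    code += 1
                elif x != ref:
                    raise ValueError(
                        f"marker {mid}, sample {sample_ids[i]}: allele {x!r} "
                        f"matches neither ref {ref!r} nor alt {alt!r}"
                    )
            genotypes[i, j] = code

    phenotypes = dict(ped_pheno)
    if phenotypes_path is not None:
        tbl = pd.read_csv(phenotypes_path, sep="\t", dtype=str)
        for r in tbl.itertuples(index=False):
            phenotypes[r.sample_id] = r.phenotype

    return GenotypeMatrix(
        sample_ids=sample_ids,
        phenotypes=phenotypes,
        markers=markers,
        genotypes=genotypes,
    )


# -- pileup TSV ---------------------------------------------------------------

PILEUP_COLUMNS = [
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "unique_support",
    "first25_support",
    "coverage",
    "mean_quality",
    "alt_fraction",
]


def write_pileups(pileups: Iterable[PileupSite], path: PathLike) -> None:
    rows = [
        (
            p.sample_id,
            p.chromosome,
            p.position_bp,
            p.ref_base,
            p.alt_base,
            p.unique_read_support,
            p.first25_support,
            p.raw_coverage,
            p.base_quality,
            p.alt_fraction,
        )
        for p in pileups
    ]
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_pileups(path: PathLike) -> List[PileupSite]:
    tbl = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(PILEUP_COLUMNS) - set(tbl.columns)
    if missing:
        raise ValueError(f"{path}: missing pileup columns {sorted(missing)}")
    return [
        PileupSite(
            sample_id=str(r.sample),
            chromosome=str(r.chrom),
            position_bp=int(r.pos),
            ref_base=str(r.ref),
            alt_base=str(r.alt),
            unique_read_support=int(r.unique_support),
            first25_support=int(r.first25_support),
            raw_coverage=int(r.coverage),
            base_quality=float(r.mean_quality),
            alt_fraction=float(r.alt_fraction),
        )
        for r in tbl.itertuples(index=False)
    ]


# -- VCF ----------------------------------------------------------------------

_GT = {"homref": "0/0", "het": "0/1", "homalt": "1/1", NOCALL: "./."}


def write_vcf(
    calls: Sequence[VariantCall],
    sample_ids: Sequence[str],
    path: PathLike,
    seed: Optional[int] = None,
    thresholds_desc: str = "",
) -> None:
    """Write calls as VCF v4.2 with per-sample genotype and rule-flag fields.

    Site FILTER is PASS when some sample passed all discovery rules, else
    ``NoSamplePass``; the per-sample FT field lists that sample's failing
    rules.  Concordant variants carry the INFO flag ``CONC``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "##fileformat=VCFv4.2",
        f"##fileDate={_dt.date.today():%Y%m%d}",
        f"##source=hydromap {__version__}",
    ]
    if seed is not None:
        lines.append(f"##hydromap_seed={seed}")
    if thresholds_desc:
        lines.append(f"##hydromap_thresholds={thresholds_desc}")
    lines += [
        '##FILTER=<ID=NoSamplePass,Description="No sample passed all caller rules">',
        '##INFO=<ID=CONC,Number=0,Type=Flag,Description="Concordant with a recessive case/control model">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=FT,Number=1,Type=String,Description="Per-sample failed caller rules (PASS if none)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    for call in calls:
        info = "CONC" if call.concordant else "."
        filt = "PASS" if call.discovered else "NoSamplePass"
        fields = [
            call.chromosome,
            str(call.position_bp),
            ".",
            call.ref_base,
            call.alt_base,
            ".",
            filt,
            info,
            "GT:FT",
        ]
        for sid in sample_ids:
            gt = _GT[call.genotypes.get(sid, NOCALL)]
            fr = call.sample_filters.get(sid)
            if fr is None:
                ft = "."
            else:
                failed = fr.failed_rules()
                ft = "PASS" if not failed else ",".join(failed)
            fields.append(f"{gt}:{ft}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


# -- shared regions -----------------------------------------------------------

def write_regions(
    regions: Sequence[SharedRegion],
    path: PathLike,
    seed: Optional[int] = None,
) -> None:
    """Tab-separated shared-region table (1-based inclusive coordinates)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# hydromap {__version__}; coordinates 1-based inclusive\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write(
            "chromosome\tstart_bp\tend_bp\tlength_bp\tn_markers\t"
            "n_cases_sharing\tn_controls_sharing\tmarker_ids\n"
        )
        for r in regions:
            fh.write(
                f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t{r.length_bp}\t"
                f"{len(r.marker_ids)}\t{r.n_cases_sharing}\t{r.n_controls_sharing}\t"
                f"{','.join(r.marker_ids)}\n"
            )
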