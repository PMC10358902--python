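"""Genotype panel I/O, strand-orientation normalization, and QC filters.

The panel is a small custom chip: ~1,000 biallelic SNPs typed on a few dozen
participants.  Genotypes arrive either as a spreadsheet-style matrix (one row
per rs number, one column per participant, two-character genotype strings) or
as a VCF.  Each chip call may carry replicate probe readings taken in forward
and reverse orientations; calls whose readings disagree after orientation
normalization are unreliable and set to missing, and participants with
pervasive inconsistencies are dropped entirely before any statistics.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

MISSING = "--"
"""Sentinel genotype for a missing / failed call; never imputed downstream."""

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

CONSEQUENCE_CLASSES = (
    "intron variant",
    "downstream",
    "upstream",
    "3'UTR",
    "missense",
    "synonymous",
    "stop-gain",
)


class GenotypeParseError(ValueError):
    """A malformed genotype entry, reported with its row/column context."""


@dataclass(frozen=True)
class SNPMeta:
    """Per-SNP annotation: alleles, nearest gene, consequence, position.

    ``pop_alt_freq`` is the published alternate-allele proportion in a
    reference population (used for the Hardy-Weinberg expected counts);
    ``None`` when unavailable.
    """

    rsid: str
    gene: str
    ref_allele: str
    alt_allele: str
    consequence: str = "intron variant"
    chrom: str = ""
    pos: int = 0
    pop_alt_freq: float | None = None

    def __post_init__(self) -> None:
        if self.ref_allele not in _NUCLEOTIDES or self.alt_allele not in _NUCLEOTIDES:
            raise ValueError(
                f"{self.rsid}: alleles must be A/C/G/T, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt allele are identical")
        if self.pop_alt_freq is not None and not 0.0 <= self.pop_alt_freq <= 1.0:
            raise ValueError(f"{self.rsid}: pop_alt_freq {self.pop_alt_freq} not in [0,1]")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref_allele, self.alt_allele)

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G SNPs are strand-ambiguous: complementing swaps alleles."""
        return _COMPLEMENT[self.ref_allele] == self.alt_allele


@dataclass(frozen=True)
class AlleleCall:
    """One participant's genotype at one SNP.

    ``genotype`` is an unordered pair stored as a sorted two-character string
    (e.g. "CT"), or :data:`MISSING`.  ``probe_calls`` holds up to six
    replicate probe readings as ``(genotype, orientation)`` pairs with
    orientation ``"F"`` (forward) or ``"R"`` (reverse).
    """

    participant_id: str
    rsid: str
    genotype: str
    probe_calls: tuple[tuple[str, str], ...] = ()
    inconsistent: bool = False

    def __post_init__(self) -> None:
        if self.genotype != MISSING:
            object.__setattr__(self, "genotype", _canonical(self.genotype))

    @property
    def is_missing(self) -> bool:
        return self.genotype == MISSING

    def alleles(self) -> tuple[str, str]:
        if self.is_missing:
            raise ValueError(f"missing call for {self.participant_id} at {self.rsid}")
        return (self.genotype[0], self.genotype[1])


def _canonical(genotype: str) -> str:
    """Sorted two-character genotype string; order of alleles carries no meaning."""
    if len(genotype) != 2 or any(a not in _NUCLEOTIDES for a in genotype):
        raise GenotypeParseError(f"invalid genotype string {genotype!r}")
    return "".join(sorted(genotype))


def _complement_genotype(genotype: str) -> str:
    if genotype == MISSING:
        return MISSING
    return _canonical("".join(_COMPLEMENT[a] for a in genotype))


@dataclass
class GenotypePanel:
    """Participant x SNP biallelic call matrix with per-SNP metadata.

    ``calls`` maps ``(participant_id, rsid)`` to an :class:`AlleleCall`; every
    rsid appearing in a call must have an entry in ``meta``.
    """

    calls: dict[tuple[str, str], AlleleCall]
    meta: dict[str, SNPMeta]
    participants: list[str]

    def __post_init__(self) -> None:
        for (pid, rsid), call in self.calls.items():
            if rsid not in self.meta:
                raise KeyError(f"call at {rsid} (participant {pid}) has no SNP metadata")
            if call.participant_id != pid or call.rsid != rsid:
                raise ValueError(f"call key {(pid, rsid)} disagrees with call fields")

    @property
    def rsids(self) -> list[str]:
        return sorted(self.meta)

    @property
    def n_snps(self) -> int:
        return len(self.meta)

    def genotype(self, participant_id: str, rsid: str) -> str:
        call = self.calls.get((participant_id, rsid))
        return MISSING if call is None else call.genotype

    def snp_genotypes(self, rsid: str) -> dict[str, str]:
        """Non-missing genotypes at ``rsid`` keyed by participant."""
        out = {}
        for pid in self.participants:
            g = self.genotype(pid, rsid)
            if g != MISSING:
                out[pid] = g
        return out

    def missingness(self, participant_id: str) -> float:
        """Fraction of this panel's SNPs missing for the participant."""
        if not self.meta:
            return 0.0
        n_miss = sum(
            1 for rsid in self.meta if self.genotype(participant_id, rsid) == MISSING
        )
        return n_miss / len(self.meta)

    def to_frame(self) -> pd.DataFrame:
        """Genotype-string matrix, participants as rows, rsids as columns."""
        data = {
            rsid: [self.genotype(pid, rsid) for pid in self.participants]
            for rsid in self.rsids
        }
        return pd.DataFrame(data, index=list(self.participants))

    def subset_snps(self, rsids: Iterable[str]) -> "GenotypePanel":
        keep = set(rsids)
        return GenotypePanel(
            calls={k: v for k, v in self.calls.items() if k[1] in keep},
            meta={r: m for r, m in self.meta.items() if r in keep},
            participants=list(self.participants),
        )

    def subset_participants(self, pids: Iterable[str]) -> "GenotypePanel":
        keep = set(pids)
        return GenotypePanel(
            calls={k: v for k, v in self.calls.items() if k[0] in keep},
            meta=dict(self.meta),
            participants=[p for p in self.participants if p in keep],
        )


# ---------------------------------------------------------------------------
# Readers / writers


def read_snp_metadata(path: str | Path) -> dict[str, SNPMeta]:
    """Read the SNP metadata sidecar CSV.

    Columns: ``rsid,gene,ref,alt,consequence,chrom,pos,pop_alt_freq`` (the
    last three optional / may be empty).
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    meta: dict[str, SNPMeta] = {}
    for _, row in df.iterrows():
        freq = row.get("pop_alt_freq", "")
        meta[row["rsid"]] = SNPMeta(
            rsid=row["rsid"],
            gene=row.get("gene", ""),
            ref_allele=row["ref"],
            alt_allele=row["alt"],
            consequence=row.get("consequence", "intron variant") or "intron variant",
            chrom=row.get("chrom", ""),
            pos=int(row["pos"]) if row.get("pos", "") else 0,
            pop_alt_freq=float(freq) if freq != "" else None,
        )
    return meta


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def read_genotypes(
    path: str | Path,
    meta: Mapping[str, SNPMeta],
    format: Literal["matrix", "vcf"] = "matrix",
) -> GenotypePanel:
    """Read a genotype panel from a matrix TSV/CSV or a VCF.

    The matrix dialect has one row per rsid, a header row of participant ids,
    and two-character genotype strings (``--`` for missing); tab or comma is
    sniffed.  VCF records must be biallelic SNVs with GT fields.  Missing
    calls are preserved, never imputed.  An rsid in the calls without an
    entry in ``meta`` is a hard error.
    """
    if format == "matrix":
        return _read_matrix(path, meta)
    if format == "vcf":
        return _read_vcf(path, meta)
    raise ValueError(f"unknown format {format!r}")


def _read_matrix(path: str | Path, meta: Mapping[str, SNPMeta]) -> GenotypePanel:
    text = Path(path).read_text(encoding="utf-8")
    delim = _sniff_delimiter(text.splitlines()[0] if text else "\t")
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    rows = [r for r in reader if r]
    if not rows:
        raise GenotypeParseError(f"{path}: empty genotype matrix")
    header = rows[0]
    participants = [c.strip() for c in header[1:]]
    calls: dict[tuple[str, str], AlleleCall] = {}
    seen_meta: dict[str, SNPMeta] = {}
    for i, row in enumerate(rows[1:], start=2):
        rsid = row[0].strip()
        if rsid not in meta:
            raise GenotypeParseError(f"{path}: row {i}: rsid {rsid!r} has no metadata")
        seen_meta[rsid] = meta[rsid]
        if len(row) - 1 != len(participants):
            raise GenotypeParseError(
                f"{path}: row {i} ({rsid}): expected {len(participants)} genotypes, "
                f"got {len(row) - 1}"
            )
        for j, (pid, cell) in enumerate(zip(participants, row[1:]), start=2):
            cell = cell.strip()
            if cell in ("", MISSING, "NN", "..", "./."):
                geno = MISSING
            else:
                try:
                    geno = _canonical(cell)
                except GenotypeParseError as exc:
                    raise GenotypeParseError(
                        f"{path}: row {i} ({rsid}), column {j} ({pid}): {exc}"
                    ) from None
            key = (pid, rsid)
            if key in calls:
                raise GenotypeParseError(f"{path}: duplicate call for {pid} at {rsid}")
            calls[key] = AlleleCall(pid, rsid, geno)
    return GenotypePanel(calls=calls, meta=seen_meta, participants=participants)


def _read_vcf(path: str | Path, meta: Mapping[str, SNPMeta]) -> GenotypePanel:
    import pysam

    calls: dict[tuple[str, str], AlleleCall] = {}
    seen_meta: dict[str, SNPMeta] = {}
    with pysam.VariantFile(str(path)) as vcf:
        participants = list(vcf.header.samples)
        for rec in vcf:
            rsid = rec.id
            if rsid is None:
                raise GenotypeParseError(f"{path}: record at {rec.chrom}:{rec.pos} has no ID")
            if rsid not in meta:
                raise GenotypeParseError(f"{path}: rsid {rsid!r} has no metadata")
            alts = rec.alts or ()
            if len(alts) != 1:
                raise GenotypeParseError(
                    f"{path}: {rsid}: only biallelic records supported, got alts {alts}"
                )
            alleles = (rec.ref, alts[0])
            if any(len(a) != 1 or a not in _NUCLEOTIDES for a in alleles):
                raise GenotypeParseError(f"{path}: {rsid}: not a SNV ({alleles})")
            seen_meta[rsid] = meta[rsid]
            for pid in participants:
                gt = rec.samples[pid].get("GT")
                if gt is None or any(g is None for g in gt):
                    geno = MISSING
                else:
                    geno = _canonical("".join(alleles[g] for g in gt))
                calls[(pid, rsid)] = AlleleCall(pid, rsid, geno)
    return GenotypePanel(calls=calls, meta=seen_meta, participants=participants)


def write_genotype_matrix(panel: GenotypePanel, path: str | Path, delim: str = "\t") -> None:
    """Write the matrix dialect (rows = rsids, columns = participants)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["rsid", *panel.participants])
        for rsid in panel.rsids:
            writer.writerow([rsid, *(panel.genotype(p, rsid) for p in panel.participants)])


def write_snp_metadata(meta: Mapping[str, SNPMeta], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["rsid", "gene", "ref", "alt", "consequence", "chrom", "pos", "pop_alt_freq"])
        for rsid in sorted(meta):
            m = meta[rsid]
            writer.writerow(
                [m.rsid, m.gene, m.ref_allele, m.alt_allele, m.consequence, m.chrom, m.pos,
                 "" if m.pop_alt_freq is None else repr(m.pop_alt_freq)]
            )


# ---------------------------------------------------------------------------
# Orientation normalization and QC filters


def normalize_orientation(call: AlleleCall, meta: SNPMeta) -> AlleleCall:
    """Express every probe reading on the forward strand and build consensus.

    Reverse-orientation probe readings are base-complemented (A<->T, C<->G).
    If the normalized replicate readings disagree, the call is flagged
    inconsistent.  Palindromic (A/T or C/G) SNPs cannot be strand-resolved
    from sequence alone: their reverse readings are trusted as reported, with
    a warning.  Idempotent: normalizing an already-forward call is a no-op.
    """
    if not call.probe_calls:
        return call
    if meta.is_palindromic and any(orient == "R" for _, orient in call.probe_calls):
        warnings.warn(
            f"{meta.rsid}: palindromic {meta.ref_allele}/{meta.alt_allele} SNP with "
            "reverse-orientation probes; strand cannot be resolved from sequence — "
            "trusting reported orientation",
            stacklevel=2,
        )
        forward = tuple((_canonical(g) if g != MISSING else g, "F") for g, _ in call.probe_calls)
    else:
        forward = tuple(
            (_complement_genotype(g) if orient == "R" else (_canonical(g) if g != MISSING else g), "F")
            for g, orient in call.probe_calls
        )
    observed = {g for g, _ in forward if g != MISSING}
    if len(observed) > 1:
        return replace(call, genotype=MISSING, probe_calls=forward, inconsistent=True)
    genotype = observed.pop() if observed else MISSING
    return replace(call, genotype=genotype, probe_calls=forward, inconsistent=False)


@dataclass
class QCAudit:
    """Record of calls set missing and participants dropped, with reasons."""

    inconsistent_calls: list[tuple[str, str]] = field(default_factory=list)
    dropped_participants: dict[str, str] = field(default_factory=dict)

    def as_records(self) -> list[dict[str, str]]:
        recs = [
            {"participant_id": p, "rsid": r, "action": "call set missing",
             "reason": "replicate probe readings disagree"}
            for p, r in self.inconsistent_calls
        ]
        recs += [
            {"participant_id": p, "rsid": "", "action": "participant dropped", "reason": why}
            for p, why in self.dropped_participants.items()
        ]
        return recs


def filter_inconsistent(
    panel: GenotypePanel, missingness_ceiling: float = 0.20
) -> tuple[GenotypePanel, QCAudit]:
    """Null out probe-inconsistent calls; drop pervasively missing participants.

    Every call's replicate probe readings are orientation-normalized; a call
    whose readings disagree is set to :data:`MISSING`.  A participant whose
    resulting missingness exceeds ``missingness_ceiling`` (default 20% of the
    panel's SNPs) is removed entirely.  The audit lists every removal.
    """
    audit = QCAudit()
    new_calls: dict[tuple[str, str], AlleleCall] = {}
    for key, call in panel.calls.items():
        norm = normalize_orientation(call, panel.meta[key[1]])
        if norm.inconsistent:
            audit.inconsistent_calls.append(key)
        new_calls[key] = norm
    cleaned = GenotypePanel(new_calls, dict(panel.meta), list(panel.participants))
    keep = []
    for pid in cleaned.participants:
        miss = cleaned.missingness(pid)
        if miss > missingness_ceiling:
            audit.dropped_participants[pid] = (
                f"missingness {miss:.1%} exceeds ceiling {missingness_ceiling:.0%}"
            )
        else:
            keep.append(pid)
    return cleaned.subset_participants(keep), audit


def remove_monomorphic(panel: GenotypePanel) -> tuple[GenotypePanel, int]:
    """Drop SNPs showing a single genotype across all non-missing calls.

    Monomorphic sites carry no between-participant information and would
    produce degenerate contingency tables downstream.  A SNP whose only
    variation is missingness is still monomorphic.  Returns the filtered
    panel and the number of SNPs removed.  Idempotent.
    """
    keep = []
    for rsid in panel.rsids:
        genotypes = set(panel.snp_genotypes(rsid).values())
        if len(genotypes) >= 2:
            keep.append(rsid)
    removed = panel.n_snps - len(keep)
    if not keep:
        warnings.warn("all SNPs monomorphic; empty panel after removal", stacklevel=2)
    return panel.subset_snps(keep), removed
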