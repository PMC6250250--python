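"""Reading, validation and harmonization of GWAS summary-statistic tables.

Two-sample Mendelian randomization needs per-SNP association estimates for
one exposure and one outcome expressed on a *common* effect allele.  This
module reads delimited summary tables (TSV default, CSV accepted), validates
each row against basic invariants (distinct single-base alleles, positive
standard error, p-value in (0, 1], frequency strictly inside (0, 1)),
aligns outcome rows to the exposure's effect allele — flipping beta signs,
complementing strands and resolving palindromic A/T / C/G variants by
allele-frequency comparison — and applies user-supplied rsID exclusion
lists for pleiotropy-sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SnpAssociation",
    "HarmonizedInstrument",
    "InstrumentSet",
    "ConfigurationError",
    "RowValidationError",
    "HarmonizationError",
    "read_association_table",
    "read_exclusion_list",
    "harmonize",
    "apply_exclusions",
    "write_instrument_table",
    "DEFAULT_COLUMNS",
    "AMBIGUOUS_EAF_WINDOW",
]

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})

#: default header names expected in input tables
DEFAULT_COLUMNS = {
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

#: effect-allele frequencies in this closed window are considered too close
#: to 0.5 to orient a palindromic SNP by frequency
AMBIGUOUS_EAF_WINDOW = (0.42, 0.58)


class ConfigurationError(ValueError):
    """A requested column mapping or file cannot be used at all."""


class RowValidationError(ValueError):
    """One or more data rows violated the association invariants."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} row(s) failed validation:\n  " + "\n  ".join(self.problems)
        )


class HarmonizationError(ValueError):
    """Exposure and outcome tables share no usable SNPs."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with a single trait.

    ``beta`` is on the trait's analysis scale: SD units for a continuous
    exposure, log odds ratio for a binary outcome.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"{self.rsid}: se must be finite and > 0")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: beta must be finite")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.rsid}: pval must lie in (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.rsid}: eaf must lie strictly in (0, 1)")

    @property
    def is_palindromic(self) -> bool:
        return frozenset({self.effect_allele, self.other_allele}) in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP aligned across exposure and outcome on a shared effect allele."""

    rsid: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    aligned_allele: str
    flipped: bool = False
    eaf_x: float | None = None
    n_x: int | None = None

    def __post_init__(self):
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValueError(f"{self.rsid}: standard errors must be > 0")
        if not (math.isfinite(self.beta_x) and math.isfinite(self.beta_y)):
            raise ValueError(f"{self.rsid}: betas must be finite")


@dataclass(frozen=True)
class InstrumentSet:
    """An ordered, rsID-unique panel of harmonized instruments."""

    instruments: tuple[HarmonizedInstrument, ...]
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    provenance: tuple[str, ...] = ()
    dispositions: dict = field(default_factory=dict)

    def __post_init__(self):
        rsids = [inst.rsid for inst in self.instruments]
        if len(rsids) != len(set(rsids)):
            raise ValueError("instrument rsids must be unique")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def rsids(self) -> list[str]:
        return [inst.rsid for inst in self.instruments]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [i.rsid for i in self.instruments],
                "beta_x": [i.beta_x for i in self.instruments],
                "se_x": [i.se_x for i in self.instruments],
                "beta_y": [i.beta_y for i in self.instruments],
                "se_y": [i.se_y for i in self.instruments],
                "aligned_allele": [i.aligned_allele for i in self.instruments],
                "flipped": [i.flipped for i in self.instruments],
            }
        )


def _sniff_delimiter(path: Path, declared: str | None) -> str:
    if declared:
        return declared
    with open(path, newline="") as fh:
        header = fh.readline()
    return "," if header.count(",") > header.count("\t") else "\t"


def read_association_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait_scale: str = "sd",
    delimiter: str | None = None,
    permissive: bool = False,
) -> list[SnpAssociation]:
    """Parse a delimited summary-statistics table into validated records.

    Parameters
    ----------
    path:
        TSV or CSV file with one row per SNP.
    column_map:
        Mapping from canonical field names (``rsid``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``) to the
        file's column names.  Defaults to the canonical names themselves.
        ``eaf`` and ``n`` are optional.
    trait_scale:
        ``"sd"`` for a standardized continuous trait, ``"log_or"`` for a
        binary trait; recorded only, the numbers are passed through.
    permissive:
        If true, invalid rows are dropped (with their reasons collected on
        the returned list's ``.rejected`` attribute) instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    if trait_scale not in {"sd", "log_or"}:
        raise ConfigurationError(f"unknown trait_scale {trait_scale!r}")
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)

    delim = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, dtype=str, comment="#")
    required = ["rsid", "effect_allele", "other_allele", "beta", "se", "pval"]
    missing = [cmap[k] for k in required if cmap[k] not in df.columns]
    if missing:
        raise ConfigurationError(f"mapped column(s) {missing} absent from {path.name}")
    has_eaf = cmap["eaf"] in df.columns
    has_n = cmap["n"] in df.columns

    records: list[SnpAssociation] = []
    problems: list[str] = []
    duplicates: list[str] = []
    best_p: dict[str, int] = {}  # rsid -> index in records (smallest p kept)
    for idx, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        rsid = str(row[cmap["rsid"]]).strip()
        try:
            ea = str(row[cmap["effect_allele"]]).strip().upper()
            oa = str(row[cmap["other_allele"]]).strip().upper()
            if ea not in VALID_BASES or oa not in VALID_BASES:
                raise ValueError(f"{rsid}: alleles must be single bases A/C/G/T (got {ea}/{oa})")
            rec = SnpAssociation(
                rsid=rsid,
                effect_allele=ea,
                other_allele=oa,
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                pval=float(row[cmap["pval"]]),
                eaf=float(row[cmap["eaf"]]) if has_eaf and _present(row[cmap["eaf"]]) else None,
                n=int(float(row[cmap["n"]])) if has_n and _present(row[cmap["n"]]) else None,
            )
        except (TypeError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
            continue
        if rec.rsid in best_p:
            # duplicate rsID: keep the row with the smallest p-value
            prev = records[best_p[rec.rsid]]
            if rec.pval < prev.pval:
                records[best_p[rec.rsid]] = rec
            duplicates.append(f"row {idx}: duplicate rsid {rec.rsid} (smaller-p row kept)")
        else:
            best_p[rec.rsid] = len(records)
            records.append(rec)

    if problems and not permissive:
        raise RowValidationError(problems)
    # expose diagnostics for callers without changing the return type
    out = _RecordList(records)
    out.rejected = problems
    out.duplicates = duplicates
    return out


class _RecordList(list):
    """List of SnpAssociation with ``.rejected`` / ``.duplicates`` diagnostics."""

    rejected: list[str] = []
    duplicates: list[str] = []


def _present(value) -> bool:
    if value is None:
        return False
    s = str(value).strip()
    return s not in {"", "NA", "nan", "NaN", "None", "."}


def read_exclusion_list(path: str | Path) -> list[str]:
    """Read a plain-text rsID list, one per line; ``#`` starts a comment."""
    rsids = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            rsids.append(line)
    return rsids


def _oriented(assoc: SnpAssociation, flip: bool) -> SnpAssociation:
    if not flip:
        return assoc
    return replace(
        assoc,
        effect_allele=assoc.other_allele,
        other_allele=assoc.effect_allele,
        beta=-assoc.beta,
        eaf=None if assoc.eaf is None else 1.0 - assoc.eaf,
    )


def harmonize(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    palindrome_policy: str = "infer_by_eaf",
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> InstrumentSet:
    """Align outcome associations to the exposure's effect allele per SNP.

    Alignment rules, applied on the rsID intersection:

    * same allele pair, same orientation — kept as is;
    * same pair, swapped orientation — outcome beta sign flipped,
      frequency replaced by its complement, ``flipped`` recorded;
    * strand-complement pair (e.g. exposure A/G vs outcome T/C) —
      outcome alleles complemented first, then aligned as above;
    * palindromic SNPs (A/T or C/G) per ``palindrome_policy``:
      ``drop`` removes them, ``keep`` assumes both studies report the same
      strand, ``infer_by_eaf`` orients by comparing effect-allele
      frequencies and drops the SNP when either frequency falls inside the
      ambiguity window around 0.5;
    * irreconcilable allele sets are dropped with an ``allele_mismatch``
      disposition.

    The returned set's ``dispositions`` counts every fate so that
    kept + dropped sums to the intersection size.
    """
    if palindrome_policy not in {"drop", "infer_by_eaf", "keep"}:
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    if not exposure or not outcome:
        raise HarmonizationError("exposure and outcome tables must be non-empty")

    out_by_rsid = {a.rsid: a for a in outcome}
    lo, hi = AMBIGUOUS_EAF_WINDOW
    dispositions = {
        "kept": 0,
        "dropped_palindromic": 0,
        "dropped_ambiguous_eaf": 0,
        "dropped_allele_mismatch": 0,
        "absent_from_outcome": 0,
    }
    instruments: list[HarmonizedInstrument] = []
    notes: list[str] = []

    for exp in exposure:
        if exp.rsid not in out_by_rsid:
            dispositions["absent_from_outcome"] += 1
            continue
        out = out_by_rsid[exp.rsid]
        exp_pair = {exp.effect_allele, exp.other_allele}
        out_pair = {out.effect_allele, out.other_allele}
        comp_pair = {COMPLEMENT[a] for a in out_pair}

        if exp.is_palindromic:
            if not out.is_palindromic or exp_pair != out_pair:
                dispositions["dropped_allele_mismatch"] += 1
                notes.append(f"{exp.rsid}: allele mismatch {exp_pair} vs {out_pair}")
                continue
            if palindrome_policy == "drop":
                dispositions["dropped_palindromic"] += 1
                continue
            if palindrome_policy == "keep":
                flip = out.effect_allele != exp.effect_allele
            else:  # infer_by_eaf
                if exp.eaf is None or out.eaf is None or lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
                    dispositions["dropped_ambiguous_eaf"] += 1
                    continue
                # frequencies agree on orientation when both are on the same
                # side of 0.5; otherwise the outcome reports the complement
                flip = (exp.eaf < 0.5) != (out.eaf < 0.5)
        else:
            if out_pair == exp_pair:
                flip = out.effect_allele != exp.effect_allele
            elif comp_pair == exp_pair:
                out = replace(
                    out,
                    effect_allele=COMPLEMENT[out.effect_allele],
                    other_allele=COMPLEMENT[out.other_allele],
                )
                flip = out.effect_allele != exp.effect_allele
            else:
                dispositions["dropped_allele_mismatch"] += 1
                notes.append(f"{exp.rsid}: allele mismatch {exp_pair} vs {out_pair}")
                continue

        out = _oriented(out, flip)
        instruments.append(
            HarmonizedInstrument(
                rsid=exp.rsid,
                beta_x=exp.beta,
                se_x=exp.se,
                beta_y=out.beta,
                se_y=out.se,
                aligned_allele=exp.effect_allele,
                flipped=flip,
                eaf_x=exp.eaf,
                n_x=exp.n,
            )
        )
        dispositions["kept"] += 1

    if not instruments:
        raise HarmonizationError("no SNPs could be harmonized between exposure and outcome")
    return InstrumentSet(
        instruments=tuple(instruments),
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        provenance=tuple(notes),
        dispositions=dispositions,
    )


def apply_exclusions(
    instrument_set: InstrumentSet, exclusion_rsids: Iterable[str]
) -> InstrumentSet:
    """Return a new set without the listed rsIDs; the input is unmodified.

    rsIDs in the list that are not in the panel are noted, not an error.
    """
    excl = set(exclusion_rsids)
    kept = tuple(i for i in instrument_set.instruments if i.rsid not in excl)
    removed = len(instrument_set.instruments) - len(kept)
    unknown = excl - set(instrument_set.rsids)
    notes = list(instrument_set.provenance) + [f"exclusions: removed {removed} SNP(s)"]
    if unknown:
        notes.append(f"exclusions: {len(unknown)} listed rsID(s) not in panel (ignored)")
    return replace(
        instrument_set,
        instruments=kept,
        provenance=tuple(notes),
        dispositions={**instrument_set.dispositions, "excluded": removed},
    )


def write_instrument_table(instrument_set: InstrumentSet, path: str | Path) -> None:
    """Write the harmonized panel back to TSV for audit."""
    instrument_set.to_frame().to_csv(path, sep="\t", index=False)
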