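"""Genotype data model, readers/writers, numeric recoding and QC filtering.

Genotypes are diploid biallelic SNP calls held as an individuals x markers
dosage matrix: 0 = homozygous for ``allele_a``, 1 = heterozygous,
2 = homozygous for ``allele_b``, ``MISSING`` (-1) = no call.  ``allele_a``
is always the alphabetically first allele observed at the marker, so parsing
is deterministic regardless of row order.  The legacy numeric coding used by
SNP-recoding tools ("1", "2", "3") maps to dosage code + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

#: strings accepted as a missing diploid call in text files
_MISSING_TOKENS = {"NN", "--", "NA", "N", "?", "./."}

#: placeholder second allele for markers where only one allele was observed
UNKNOWN_ALLELE = "N"


class GenotypeParseError(ValueError):
    """Malformed genotype file (row width, bad token, duplicate id)."""


class GenotypeDataError(ValueError):
    """Structurally valid file with inconsistent genetic content."""


@dataclass(frozen=True)
class MarkerInfo:
    """Identity and allele labels of one SNP."""

    marker_id: str
    chromosome: str = "0"
    position_bp: int = 0  # 1-based base pairs
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(f"negative position for {self.marker_id}")
        if self.allele_a == self.allele_b:
            raise ValueError(
                f"marker {self.marker_id}: allele_a == allele_b ({self.allele_a})"
            )


@dataclass
class GenotypeMatrix:
    """Individuals x markers diploid dosage matrix with missingness."""

    individuals: list[str]
    markers: list[MarkerInfo]
    calls: np.ndarray  # (n_individuals, n_markers) int8; MISSING = -1

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = len(self.individuals), len(self.markers)
        if self.calls.shape != (n, m):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n} individuals, {m} markers)"
            )
        if len(set(self.individuals)) != n:
            raise GenotypeDataError("duplicate individual ids")
        ids = [mk.marker_id for mk in self.markers]
        if len(set(ids)) != m:
            raise GenotypeDataError("duplicate marker ids")
        valid = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not valid.all():
            raise ValueError("calls must be 0/1/2 or MISSING")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def allele_b_freq(self) -> np.ndarray:
        """Per-marker frequency of allele_b over non-missing calls (NaN if none)."""
        mask = self.calls != MISSING
        n_called = mask.sum(axis=0)
        dosage_sum = np.where(mask, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, dosage_sum / (2.0 * n_called), np.nan)

    def allele_a_freq(self) -> np.ndarray:
        return 1.0 - self.allele_b_freq()

    def call_rate(self) -> np.ndarray:
        return self.called_mask().mean(axis=0)

    def maf(self) -> np.ndarray:
        q = self.allele_b_freq()
        return np.minimum(q, 1.0 - q)

    def subset(
        self,
        individuals: Sequence[str] | None = None,
        marker_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = (
            [self.individuals.index(i) for i in individuals]
            if individuals is not None
            else list(range(self.n_individuals))
        )
        if marker_ids is not None:
            pos = {m: j for j, m in enumerate(self.marker_ids)}
            cols = [pos[m] for m in marker_ids]
        else:
            cols = list(range(self.n_markers))
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in rows],
            markers=[self.markers[j] for j in cols],
            calls=self.calls[np.ix_(rows, cols)].copy(),
        )


@dataclass
class GroupAssignment:
    """Mapping individual id -> group label (e.g. seed company)."""

    mapping: dict[str, str]

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return [i for i, g in self.mapping.items() if g == group]

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        missing = set(self.mapping) - set(matrix.individuals)
        if missing:
            raise GenotypeDataError(
                f"group assignment names unknown individuals: {sorted(missing)}"
            )
        for g in self.groups():
            if not self.members(g):
                raise GenotypeDataError(f"empty group {g!r}")


@dataclass
class QCReport:
    """Per-marker call rate / MAF with pass-fail status and reasons."""

    table: pd.DataFrame  # columns: marker_id call_rate maf status reason
    markers_in: int
    markers_passing: int
    markers_failing: int

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# parsing helpers


def _decode_call(token: str, marker_id: str) -> tuple[str, ...]:
    """Return the (unordered) allele letters of one diploid call, () if missing."""
    token = token.strip()
    if not token or token.upper() in _MISSING_TOKENS:
        return ()
    if token in {"0", "1", "2"}:
        # dosage digits are resolved later once alleles are known
        return ("<dosage>", token)
    if len(token) == 2 and token.isalpha():
        return tuple(sorted(token.upper()))
    raise GenotypeParseError(f"unparseable call {token!r} at marker {marker_id}")


def _matrix_from_letter_calls(
    individuals: list[str],
    marker_ids: list[str],
    raw: list[list[tuple[str, ...]]],
    marker_meta: Mapping[str, tuple[str, int]] | None = None,
) -> GenotypeMatrix:
    """Infer alleles per marker and build the dosage matrix.

    ``raw`` is marker-major: raw[j][i] is the decoded call tuple of
    individual i at marker j.
    """
    n, m = len(individuals), len(marker_ids)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    markers: list[MarkerInfo] = []
    for j, mid in enumerate(marker_ids):
        observed: set[str] = set()
        dosage_mode = False
        for cell in raw[j]:
            if not cell:
                continue
            if cell[0] == "<dosage>":
                dosage_mode = True
            else:
                observed.update(cell)
        if len(observed) > 2:
            raise GenotypeDataError(
                f"marker {mid}: more than two alleles observed ({sorted(observed)})"
            )
        alleles = sorted(observed)
        if dosage_mode and not alleles:
            alleles = ["A", "B"]  # dosage files carry no letter information
        if len(alleles) == 0:
            alleles = ["A", UNKNOWN_ALLELE]
        elif len(alleles) == 1:
            alleles = (
                [alleles[0], UNKNOWN_ALLELE]
                if alleles[0] != UNKNOWN_ALLELE
                else ["A", UNKNOWN_ALLELE]
            )
        a, b = alleles[0], alleles[1]
        chrom, pos = ("0", 0)
        if marker_meta and mid in marker_meta:
            chrom, pos = marker_meta[mid]
        markers.append(
            MarkerInfo(
                marker_id=mid, chromosome=str(chrom), position_bp=int(pos),
                allele_a=a, allele_b=b,
            )
        )
        for i, cell in enumerate(raw[j]):
            if not cell:
                continue
            if cell[0] == "<dosage>":
                calls[i, j] = int(cell[1])
            else:
                calls[i, j] = sum(1 for al in cell if al == b)
    return GenotypeMatrix(individuals=individuals, markers=markers, calls=calls)


def read_genotypes(
    path: str | Path,
    format: str = "individual-major-tsv",
    marker_map: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a genotype file in one of the supported text dialects.

    ``individual-major-tsv``: header ``id<TAB>marker1...``, one row per
    individual, calls as two-letter diploid strings (AA, AG), dosage digits
    0/1/2, or a missing token (NN, --, NA).

    ``hapmap``: marker-major, columns ``rs# alleles chrom pos`` followed by
    one column per individual with diploid letter calls.

    An optional ``marker_map`` TSV (``marker_id chromosome position``)
    supplies coordinates for the individual-major dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, tuple[str, int]] = {}
    if marker_map is not None:
        mm = pd.read_csv(marker_map, sep="\t", dtype=str)
        for _, row in mm.iterrows():
            meta[row.iloc[0]] = (str(row.iloc[1]), int(row.iloc[2]))

    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")

    if format == "individual-major-tsv":
        header = lines[0].split("\t")
        marker_ids = header[1:]
        individuals: list[str] = []
        rows: list[list[tuple[str, ...]]] = []
        for lineno, ln in enumerate(lines[1:], start=2):
            fields = ln.split("\t")
            if len(fields) != len(header):
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            ind = fields[0]
            if ind in individuals:
                raise GenotypeDataError(f"duplicate individual id {ind!r}")
            individuals.append(ind)
            rows.append(
                [_decode_call(tok, marker_ids[j]) for j, tok in enumerate(fields[1:])]
            )
        raw = [[rows[i][j] for i in range(len(individuals))] for j in range(len(marker_ids))]
        return _matrix_from_letter_calls(individuals, marker_ids, raw, meta)

    if format == "hapmap":
        header = lines[0].split("\t")
        if len(header) < 5:
            raise GenotypeParseError(f"{path}: hapmap header needs >=5 columns")
        individuals = header[4:]
        if len(set(individuals)) != len(individuals):
            raise GenotypeDataError("duplicate individual id in hapmap header")
        marker_ids = []
        raw = []
        for lineno, ln in enumerate(lines[1:], start=2):
            fields = ln.split("\t")
            if len(fields) != len(header):
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            mid, _alleles, chrom, pos = fields[0], fields[1], fields[2], fields[3]
            meta.setdefault(mid, (chrom, int(pos)))
            marker_ids.append(mid)
            raw.append([_decode_call(tok, mid) for tok in fields[4:]])
        return _matrix_from_letter_calls(individuals, marker_ids, raw, meta)

    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the individual-major TSV dialect with two-letter diploid calls."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(matrix.marker_ids) + "\n")
        for i, ind in enumerate(matrix.individuals):
            toks = []
            for j, mk in enumerate(matrix.markers):
                c = matrix.calls[i, j]
                if c == MISSING:
                    toks.append("NN")
                elif c == 0:
                    toks.append(mk.allele_a * 2)
                elif c == 1:
                    toks.append("".join(sorted((mk.allele_a, mk.allele_b))))
                else:
                    toks.append(mk.allele_b * 2)
            fh.write(ind + "\t" + "\t".join(toks) + "\n")


def read_groups(path: str | Path) -> GroupAssignment:
    """Read a ``individual_id<TAB>group`` table (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if list(df.iloc[0]) == ["individual_id", "group"]:
        df = df.iloc[1:]
    return GroupAssignment(mapping=dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_groups(groups: GroupAssignment, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("individual_id\tgroup\n")
        for ind, g in groups.mapping.items():
            fh.write(f"{ind}\t{g}\n")


# ---------------------------------------------------------------------------
# recoding


def recode_numeric(matrix: GenotypeMatrix) -> np.ndarray:
    """Legacy numeric coding: dosage + 1 -> 1/2/3; missing stays MISSING."""
    out = matrix.calls.astype(np.int8) + 1
    out[matrix.calls == MISSING] = MISSING
    return out


def decode_numeric(
    codes: np.ndarray,
    individuals: Sequence[str],
    markers: Sequence[MarkerInfo],
) -> GenotypeMatrix:
    """Inverse of :func:`recode_numeric`."""
    codes = np.asarray(codes)
    calls = (codes - 1).astype(np.int8)
    calls[codes == MISSING] = MISSING
    return GenotypeMatrix(list(individuals), list(markers), calls)


# ---------------------------------------------------------------------------
# QC


def qc_filter(
    matrix: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Retain markers with call rate >= ``min_call_rate`` and MAF >= ``min_maf``.

    Both thresholds are inclusive.  MAF is computed over the non-missing
    calls of all individuals in ``matrix``.  Marker order is preserved.
    """
    if matrix.n_markers == 0 or matrix.n_individuals == 0:
        raise GenotypeDataError("cannot QC an empty genotype matrix")
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    cr = matrix.call_rate()
    maf = matrix.maf()
    rows = []
    keep = []
    for j, mk in enumerate(matrix.markers):
        reasons = []
        if cr[j] < min_call_rate:
            reasons.append("call_rate")
        # an all-missing marker has undefined MAF and already fails call rate
        if not np.isnan(maf[j]) and maf[j] < min_maf:
            reasons.append("maf")
        ok = not reasons
        keep.append(ok)
        rows.append(
            {
                "marker_id": mk.marker_id,
                "call_rate": cr[j],
                "maf": maf[j],
                "status": "pass" if ok else "fail",
                "reason": ";".join(reasons),
            }
        )
    table = pd.DataFrame(rows)
    kept_ids = [mk.marker_id for mk, k in zip(matrix.markers, keep) if k]
    report = QCReport(
        table=table,
        markers_in=matrix.n_markers,
        markers_passing=len(kept_ids),
        markers_failing=matrix.n_markers - len(kept_ids),
    )
    filtered = matrix.subset(marker_ids=kept_ids)
    return filtered, report


# ---------------------------------------------------------------------------
# panel intersection


def _reconciled_flip(a: MarkerInfo, b: MarkerInfo) -> bool | None:
    """Whether b's dosages must be flipped to match a's orientation.

    Returns None when the allele sets cannot be reconciled.  The unknown
    placeholder matches any allele.
    """
    known_a = {x for x in (a.allele_a, a.allele_b) if x != UNKNOWN_ALLELE}
    known_b = {x for x in (b.allele_a, b.allele_b) if x != UNKNOWN_ALLELE}
    if not known_b or not known_a:
        return False
    if not known_b <= known_a and not known_a <= known_b:
        return None
    # same orientation if b.allele_a corresponds to a.allele_a
    if b.allele_a == a.allele_a or b.allele_b == a.allele_b:
        return False
    if b.allele_a == a.allele_b or b.allele_b == a.allele_a:
        return True
    return None


def intersect_panels(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Union of individuals restricted to the markers shared by both panels.

    Dosages of ``b`` are re-oriented so allele_a/allele_b agree with ``a``;
    the marker order is the order in ``a``.
    """
    overlap = set(a.individuals) & set(b.individuals)
    if overlap:
        raise GenotypeDataError(
            f"individual ids present in both panels: {sorted(overlap)[:5]}"
        )
    b_idx = {m.marker_id: j for j, m in enumerate(b.markers)}
    shared = [mk for mk in a.markers if mk.marker_id in b_idx]
    if not shared:
        raise GenotypeDataError("no shared markers between panels")
    individuals = a.individuals + b.individuals
    calls = np.full((len(individuals), len(shared)), MISSING, dtype=np.int8)
    markers: list[MarkerInfo] = []
    a_pos = {m.marker_id: j for j, m in enumerate(a.markers)}
    for jj, mk in enumerate(shared):
        ja, jb = a_pos[mk.marker_id], b_idx[mk.marker_id]
        flip = _reconciled_flip(mk, b.markers[jb])
        if flip is None:
            raise GenotypeDataError(
                f"marker {mk.marker_id}: irreconcilable alleles "
                f"{mk.allele_a}/{mk.allele_b} vs "
                f"{b.markers[jb].allele_a}/{b.markers[jb].allele_b}"
            )
        calls[: a.n_individuals, jj] = a.calls[:, ja]
        col_b = b.calls[:, jb].copy()
        if flip:
            mask = col_b != MISSING
            col_b[mask] = 2 - col_b[mask]
        calls[a.n_individuals :, jj] = col_b
        # prefer the marker that knows both alleles
        chosen = mk
        if UNKNOWN_ALLELE in (mk.allele_a, mk.allele_b):
            other = b.markers[jb]
            if UNKNOWN_ALLELE not in (other.allele_a, other.allele_b):
                oa, ob = other.allele_a, other.allele_b
                if flip:
                    oa, ob = ob, oa
                chosen = replace(mk, allele_a=oa, allele_b=ob)
        markers.append(chosen)
    return GenotypeMatrix(individuals=individuals, markers=markers, calls=calls)
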