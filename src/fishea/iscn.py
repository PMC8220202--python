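"""Parsing, serialization and recurrence mining for ISCN karyotype strings.

The dialect covered is the one produced by conventional G-band karyotyping of
the Barrett's epithelial carcinogenesis (BEC) cell-line replicates: a modal
chromosome count, a sex designation, and a comma-separated list of aberration
tokens drawn from

* whole-chromosome gain ``+20`` and loss ``-Y``
* additional material of unknown origin ``add(4)(p16.1)``
* isochromosome ``i(8)(q10)``
* duplication ``dup(11)(q13q25)``
* two- or three-way translocation ``t(2;10;16)(p22;q22;q22)``

All other ISCN constructs (``der``, ``ins``, ``inv``, mosaic ``[n]`` cell
counts, ``?`` uncertainty) are rejected with a :class:`KaryotypeParseError`
naming the offending token.  Whitespace is not significant anywhere in this
dialect and is stripped before tokenizing, so strings printed with stray
spaces (``", + 20, + 20"``) parse identically to their compact forms.

Repeated tokens are kept as a multiset: ``+20,+20`` is two gain entries, which
is what distinguishes trisomy from tetrasomy of the same chromosome when
counting recurrence across replicates.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "BandAddress",
    "Aberration",
    "Karyotype",
    "KaryotypeParseError",
    "Resolution",
    "RecurrentAberration",
    "parse_karyotype",
    "parse_aberration",
    "format_karyotype",
    "format_aberration",
    "match_aberration",
    "find_recurrent",
    "diff_karyotypes",
]

Resolution = Literal["exact", "major_band", "chromosomes_only"]
RESOLUTIONS: tuple[str, ...] = ("exact", "major_band", "chromosomes_only")

_VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])

_BAND_RE = re.compile(r"([pq])(\d+(?:\.\d+)?)")
_GAIN_RE = re.compile(r"^\+(\w+)$")
_LOSS_RE = re.compile(r"^-(\w+)$")
_ADD_RE = re.compile(r"^add\(([^)]*)\)\(([^)]*)\)$")
_ISO_RE = re.compile(r"^i\(([^)]*)\)\(([^)]*)\)$")
_DUP_RE = re.compile(r"^dup\(([^)]*)\)\(([^)]*)\)$")
_TRANS_RE = re.compile(r"^t\(([^)]*)\)\(([^)]*)\)$")
_SEX_RE = re.compile(r"^[XY]+$")


class KaryotypeParseError(ValueError):
    """Raised when an ISCN string (or one token of it) cannot be parsed.

    Attributes
    ----------
    token : str | None
        The offending token, if the error is local to one token.
    position : int | None
        Zero-based index of the token within the comma-separated fields.
    """

    def __init__(self, message: str, token: str | None = None, position: int | None = None):
        self.token = token
        self.position = position
        if token is not None:
            message = f"{message}: {token!r}" + (
                f" (field {position})" if position is not None else ""
            )
        super().__init__(message)


def _check_chromosome(label: str, token: str | None = None) -> str:
    if label not in _VALID_CHROMOSOMES:
        raise KaryotypeParseError(f"invalid chromosome label {label!r}", token=token)
    return label


@dataclass(frozen=True, order=True)
class BandAddress:
    """A cytogenetic band coordinate: arm (p short / q long) plus band digits."""

    arm: str
    band: str

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if not re.fullmatch(r"\d+(\.\d+)?", self.band):
            raise ValueError(f"band must match digits[.digits], got {self.band!r}")

    @property
    def major(self) -> str:
        """Arm plus the first band digit, e.g. q22 and q21 both give 'q2'."""
        return self.arm + self.band[0]

    def __str__(self) -> str:
        return self.arm + self.band

    @classmethod
    def parse(cls, text: str) -> "BandAddress":
        m = _BAND_RE.fullmatch(text)
        if m is None:
            raise KaryotypeParseError("invalid band address", token=text)
        return cls(arm=m.group(1), band=m.group(2))


_ARITY = {
    # kind -> (min chromosomes, max chromosomes, bands per chromosome rule)
    "gain": (1, 1, 0),
    "loss": (1, 1, 0),
    "add": (1, 1, 1),
    "iso": (1, 1, 1),
    "dup": (1, 1, 2),
    "translocation": (2, None, "per_chromosome"),
}


@dataclass(frozen=True)
class Aberration:
    """One structural or numerical chromosome aberration.

    ``kind`` is one of gain, loss, add, iso, dup, translocation.  For a
    translocation the bands align positionally with the chromosomes; for a
    dup the two bands delimit the duplicated span on the single chromosome.
    """

    kind: str
    chromosomes: tuple[str, ...]
    bands: tuple[BandAddress, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        object.__setattr__(self, "bands", tuple(self.bands))
        if self.kind not in _ARITY:
            raise ValueError(f"unknown aberration kind {self.kind!r}")
        for c in self.chromosomes:
            _check_chromosome(c)
        lo, hi, band_rule = _ARITY[self.kind]
        n = len(self.chromosomes)
        if n < lo or (hi is not None and n > hi):
            raise ValueError(f"{self.kind} takes {lo}{'+' if hi is None else ''} chromosome(s), got {n}")
        expected = n if band_rule == "per_chromosome" else band_rule
        if len(self.bands) != expected:
            raise ValueError(
                f"{self.kind} over {n} chromosome(s) requires {expected} band(s), got {len(self.bands)}"
            )

    def __str__(self) -> str:
        return format_aberration(self)


@dataclass(frozen=True)
class Karyotype:
    """A parsed karyotype: modal count, sex designation, ordered aberrations."""

    modal_count: int
    sex_designation: str
    aberrations: tuple[Aberration, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "aberrations", tuple(self.aberrations))
        if self.modal_count < 1:
            raise ValueError("modal count must be >= 1")
        if not self.sex_designation:
            raise ValueError("sex designation must be nonempty")

    def __str__(self) -> str:
        return format_karyotype(self)


# ---------------------------------------------------------------------------
# parsing


def parse_aberration(token: str, position: int | None = None) -> Aberration:
    """Parse a single ISCN aberration token such as ``t(2;10;16)(p22;q22;q22)``."""
    token = re.sub(r"\s+", "", token)
    # unicode minus variants occasionally survive text extraction
    token = token.replace("−", "-").replace("–", "-")
    if not token:
        raise KaryotypeParseError("empty aberration token", token=token, position=position)

    m = _GAIN_RE.fullmatch(token)
    if m:
        return Aberration("gain", (_check_chromosome(m.group(1), token),))
    m = _LOSS_RE.fullmatch(token)
    if m:
        return Aberration("loss", (_check_chromosome(m.group(1), token),))
    m = _ADD_RE.fullmatch(token)
    if m:
        return Aberration("add", (_check_chromosome(m.group(1), token),), (BandAddress.parse(m.group(2)),))
    m = _ISO_RE.fullmatch(token)
    if m:
        return Aberration("iso", (_check_chromosome(m.group(1), token),), (BandAddress.parse(m.group(2)),))
    m = _DUP_RE.fullmatch(token)
    if m:
        bands = _BAND_RE.findall(m.group(2))
        joined = "".join(a + b for a, b in bands)
        if len(bands) != 2 or joined != m.group(2):
            raise KaryotypeParseError("dup requires exactly two band addresses", token=token, position=position)
        return Aberration(
            "dup",
            (_check_chromosome(m.group(1), token),),
            tuple(BandAddress(arm=a, band=b) for a, b in bands),
        )
    m = _TRANS_RE.fullmatch(token)
    if m:
        chroms = tuple(_check_chromosome(c, token) for c in m.group(1).split(";"))
        bands = tuple(BandAddress.parse(b) for b in m.group(2).split(";"))
        if len(chroms) < 2:
            raise KaryotypeParseError("translocation requires >= 2 chromosomes", token=token, position=position)
        if len(bands) != len(chroms):
            raise KaryotypeParseError(
                f"translocation lists {len(chroms)} chromosomes but {len(bands)} bands",
                token=token,
                position=position,
            )
        return Aberration("translocation", chroms, bands)

    raise KaryotypeParseError("unrecognized aberration token", token=token, position=position)


def parse_karyotype(text: str) -> Karyotype:
    """Parse an ISCN karyotype string into a :class:`Karyotype`.

    The first comma-separated field is the modal chromosome count, the second
    the sex designation (a string over {X, Y}, stored verbatim); every
    remaining field is one aberration token.  Whitespace anywhere in the
    string is ignored.

    >>> k = parse_karyotype("48,XY,i(8)(q10),t(2;10;16)(p22;q22;q22),+20,+20")
    >>> k.modal_count, len(k.aberrations)
    (48, 4)
    """
    compact = re.sub(r"\s+", "", text)
    if not compact:
        raise KaryotypeParseError("empty karyotype string")
    fields = compact.split(",")
    if len(fields) < 2:
        raise KaryotypeParseError("karyotype must have at least modal count and sex fields", token=text)
    try:
        modal = int(fields[0])
    except ValueError:
        raise KaryotypeParseError("modal count is not an integer", token=fields[0], position=0) from None
    if modal < 1:
        raise KaryotypeParseError("modal count must be >= 1", token=fields[0], position=0)
    sex = fields[1]
    if not _SEX_RE.fullmatch(sex):
        raise KaryotypeParseError("sex designation must be a string over {X, Y}", token=sex, position=1)
    aberrations = tuple(
        parse_aberration(tok, position=i) for i, tok in enumerate(fields[2:], start=2)
    )
    return Karyotype(modal_count=modal, sex_designation=sex, aberrations=aberrations)


# ---------------------------------------------------------------------------
# serialization


def format_aberration(a: Aberration) -> str:
    if a.kind == "gain":
        return f"+{a.chromosomes[0]}"
    if a.kind == "loss":
        return f"-{a.chromosomes[0]}"
    if a.kind == "add":
        return f"add({a.chromosomes[0]})({a.bands[0]})"
    if a.kind == "iso":
        return f"i({a.chromosomes[0]})({a.bands[0]})"
    if a.kind == "dup":
        return f"dup({a.chromosomes[0]})({a.bands[0]}{a.bands[1]})"
    if a.kind == "translocation":
        return "t({})({})".format(";".join(a.chromosomes), ";".join(str(b) for b in a.bands))
    raise ValueError(f"unknown aberration kind {a.kind!r}")  # pragma: no cover


def format_karyotype(k: Karyotype) -> str:
    """Serialize a :class:`Karyotype` back to an ISCN string (round-trip safe)."""
    parts = [str(k.modal_count), k.sex_designation]
    parts.extend(format_aberration(a) for a in k.aberrations)
    return ",".join(parts)


# ---------------------------------------------------------------------------
# comparison and recurrence


def _aberration_key(a: Aberration, resolution: str):
    if resolution == "exact":
        return (a.kind, a.chromosomes, a.bands)
    if resolution == "major_band":
        return (a.kind, a.chromosomes, tuple(b.major for b in a.bands))
    if resolution == "chromosomes_only":
        return (a.kind, a.chromosomes)
    raise ValueError(f"unknown resolution {resolution!r}; expected one of {RESOLUTIONS}")


def match_aberration(a: Aberration, b: Aberration, resolution: Resolution = "exact") -> bool:
    """Whether two aberrations are the same event at the given band resolution.

    ``exact`` requires full band equality; ``major_band`` compares only the
    arm and first band digit (so q21 vs q22 match, reconciling sub-band
    variants of one recurrent event); ``chromosomes_only`` ignores bands
    entirely.  The relation is an equivalence at every resolution and
    exact => major_band => chromosomes_only.
    """
    return _aberration_key(a, resolution) == _aberration_key(b, resolution)


@dataclass(frozen=True)
class RecurrentAberration:
    """One recurrence group: a representative event with per-karyotype tallies.

    ``count`` is the number of input karyotypes carrying the event (at least
    ``min_multiplicity`` copies); ``total_occurrences`` counts every token, so
    a karyotype with ``+20,+20`` contributes 1 to ``count`` but 2 here.
    """

    representative: Aberration
    count: int
    total_occurrences: int
    per_karyotype: tuple[int, ...]


def find_recurrent(
    karyotypes: Sequence[Karyotype],
    min_count: int = 2,
    resolution: Resolution = "exact",
    min_multiplicity: int = 1,
) -> list[RecurrentAberration]:
    """Group aberrations across karyotypes and return the recurrent ones.

    Aberrations are grouped by :func:`match_aberration` equivalence at the
    given resolution.  A karyotype is a member of a group when it carries at
    least ``min_multiplicity`` copies of the event (``min_multiplicity=2``
    selects e.g. doubled chromosome gains).  Groups with membership
    >= ``min_count`` are returned sorted by descending count, then by the
    serialized representative.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if min_multiplicity < 1:
        raise ValueError("min_multiplicity must be >= 1")
    reps: dict = {}
    per_k: dict = {}
    for i, k in enumerate(karyotypes):
        counts = Counter(_aberration_key(a, resolution) for a in k.aberrations)
        for a in k.aberrations:
            reps.setdefault(_aberration_key(a, resolution), a)
        for key, n in counts.items():
            per_k.setdefault(key, [0] * len(karyotypes))[i] = n
    out = []
    for key, rep in reps.items():
        tallies = tuple(per_k[key])
        count = sum(1 for n in tallies if n >= min_multiplicity)
        if count >= min_count:
            out.append(
                RecurrentAberration(
                    representative=rep,
                    count=count,
                    total_occurrences=sum(tallies),
                    per_karyotype=tallies,
                )
            )
    out.sort(key=lambda g: (-g.count, format_aberration(g.representative)))
    return out


def diff_karyotypes(
    a: Karyotype, b: Karyotype, resolution: Resolution = "exact"
) -> tuple[list[Aberration], list[Aberration]]:
    """Multiset difference of aberrations between two karyotypes.

    Returns ``(gained, lost)``: events present in ``b`` but not ``a`` and vice
    versa, matched at the given resolution.  ``diff_karyotypes(k, k)`` is
    empty; each list is sorted by serialization.
    """
    ka = Counter(_aberration_key(x, resolution) for x in a.aberrations)
    kb = Counter(_aberration_key(x, resolution) for x in b.aberrations)
    reps: dict = {}
    for x in list(a.aberrations) + list(b.aberrations):
        reps.setdefault(_aberration_key(x, resolution), x)
    gained = [reps[key] for key, n in (kb - ka).items() for _ in range(n)]
    lost = [reps[key] for key, n in (ka - kb).items() for _ in range(n)]
    gained.sort(key=format_aberration)
    lost.sort(key=format_aberration)
    return gained, lost
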