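"""Isoelectric-point calculation from sequence.

The net charge of a protein at a given pH is modelled as a sum of independent
Henderson–Hasselbalch terms, one per ionizable group: the N-terminus and the
basic side chains (H, K, R) contribute

    +1 / (1 + 10**(pH - pKa))

while the C-terminus and the acidic side chains (D, E, C, Y) contribute

    -1 / (1 + 10**(pKa - pH)).

The pI is the pH at which this net charge crosses zero; because every term is
strictly decreasing in pH, the zero is unique and is located by bisection on
[0, 14].  Ambiguity letters (B, Z, X) and selenocysteine (U) carry no
ionizable group and contribute nothing.

Two pKa schemes ship as data files: a Bjellqvist-style set matching the
ExPASy ProtParam constants (with residue-specific N-terminal pKas) and an
EMBOSS-style alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ParameterError, PiscapeError, ValidationError
from .sequence_io import ProteinRecord, validate_sequence

_SIDE_CHAIN_RESIDUES = ("D", "E", "C", "Y", "H", "K", "R")
_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")

#: default bisection tolerance, pH units
DEFAULT_TOL = 0.001


@dataclass(frozen=True)
class PKaScheme:
    """Named set of dissociation constants for the ionizable groups."""

    name: str
    side_chain: dict[str, float]
    c_term: float
    n_term_default: float
    n_term_by_residue: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.side_chain) != set(_SIDE_CHAIN_RESIDUES):
            raise ValidationError(
                f"scheme {self.name!r}: side_chain must cover exactly "
                f"{set(_SIDE_CHAIN_RESIDUES)}, got {set(self.side_chain)}"
            )
        values = [self.c_term, self.n_term_default, *self.side_chain.values(),
                  *self.n_term_by_residue.values()]
        if not all(0.0 < v < 14.0 for v in values):
            raise ValidationError(f"scheme {self.name!r}: pKa values must lie in (0, 14)")

    def n_term_pka(self, first_residue: str) -> float:
        return self.n_term_by_residue.get(first_residue, self.n_term_default)


def _parse_scheme_text(text: str, source: str) -> PKaScheme:
    fields: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        fields[key.strip()] = value.strip()
    try:
        side_chain = {
            r: float(fields[f"side_chain.{r}"]) for r in _SIDE_CHAIN_RESIDUES
        }
        scheme = PKaScheme(
            name=fields["name"],
            side_chain=side_chain,
            c_term=float(fields["c_term"]),
            n_term_default=float(fields["n_term_default"]),
            n_term_by_residue={
                k.split(".", 1)[1]: float(v)
                for k, v in fields.items()
                if k.startswith("n_term.")
            },
        )
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"malformed pKa scheme file {source}: {exc}") from exc
    return scheme


def load_scheme(name_or_path: str | Path = "bjellqvist") -> PKaScheme:
    """Load a pKa scheme by built-in name (``bjellqvist``, ``emboss``) or file path."""
    name = str(name_or_path)
    builtin = resources.files("piscape.data").joinpath(f"pka_{name}.tsv")
    if builtin.is_file():
        return _parse_scheme_text(builtin.read_text(), source=f"builtin:{name}")
    path = Path(name_or_path)
    if path.is_file():
        return _parse_scheme_text(path.read_text(), source=str(path))
    raise ParameterError(f"unknown pKa scheme {name_or_path!r}")


class _ChargeModel:
    """Composition-level charge evaluator: pKa/count arrays for one sequence.

    Charge depends only on residue composition plus the first residue's
    identity (through the N-terminal pKa), so a counts representation makes
    repeated evaluations during bisection cheap.
    """

    __slots__ = ("pos_pka", "pos_n", "neg_pka", "neg_n")

    def __init__(self, sequence: str, scheme: PKaScheme):
        counts = {r: sequence.count(r) for r in _SIDE_CHAIN_RESIDUES}
        self.pos_pka = [scheme.n_term_pka(sequence[0])] + [
            scheme.side_chain[r] for r in _BASIC
        ]
        self.pos_n = [1] + [counts[r] for r in _BASIC]
        self.neg_pka = [scheme.c_term] + [scheme.side_chain[r] for r in _ACIDIC]
        self.neg_n = [1] + [counts[r] for r in _ACIDIC]

    def charge(self, ph: float) -> float:
        pos = sum(
            n / (1.0 + 10.0 ** (ph - pka))
            for n, pka in zip(self.pos_n, self.pos_pka)
            if n
        )
        neg = sum(
            n / (1.0 + 10.0 ** (pka - ph))
            for n, pka in zip(self.neg_n, self.neg_pka)
            if n
        )
        return pos - neg

    def pi_raw(self, tol: float) -> float:
        lo, hi = 0.0, 14.0
        f_lo, f_hi = self.charge(lo), self.charge(hi)
        if f_lo < 0.0 or f_hi > 0.0:
            # cannot happen for a sequence with both termini; defensive guard
            raise PiscapeError("net charge has no sign change on [0, 14]")
        while hi - lo >= tol:
            mid = 0.5 * (lo + hi)
            if self.charge(mid) > 0.0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def pi(self, tol: float) -> float:
        return round(self.pi_raw(tol), 3)


def net_charge(sequence: str, ph: float, scheme: PKaScheme | None = None) -> float:
    """Net charge (elementary-charge units) of *sequence* at *ph*."""
    validate_sequence(sequence)
    if not 0.0 <= ph <= 14.0:
        raise ParameterError(f"pH must lie in [0, 14], got {ph}")
    scheme = scheme or load_scheme()
    return _ChargeModel(sequence, scheme).charge(ph)


def calc_pi(
    sequence: str,
    scheme: PKaScheme | None = None,
    tol: float = DEFAULT_TOL,
) -> float:
    """Isoelectric point of *sequence*: the zero of the net charge, by bisection.

    The bracket [0, 14] is halved until its width drops below *tol*
    (default 0.001 pH); the result is reported to three decimals.
    """
    validate_sequence(sequence)
    if tol <= 0.0:
        raise ParameterError(f"tol must be positive, got {tol}")
    scheme = scheme or load_scheme()
    return _ChargeModel(sequence, scheme).pi(tol)


def batch_pi(
    records: list[ProteinRecord],
    scheme: PKaScheme | None = None,
    tol: float = DEFAULT_TOL,
) -> list[ProteinRecord]:
    """Return records with ``pi`` set, order preserved."""
    scheme = scheme or load_scheme()
    out = []
    for rec in records:
        try:
            out.append(rec.with_pi(calc_pi(rec.sequence, scheme, tol)))
        except PiscapeError as exc:
            raise type(exc)(f"record {rec.id!r}: {exc}") from exc
    return out
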