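"""Protein net-charge model and cationic tag designer.

The charge model is the conventional "expected charge" at neutral pH: each
lysine (K) and arginine (R) contributes +1, each aspartate (D) and glutamate
(E) contributes -1, histidine and all other residues are neutral, and chain
termini are ignored.  Under this convention the 9-mer cationic tag unit
``GGSKKRKKR`` carries +6 (4 K + 2 R), so appending ``n`` repeats raises a
fusion's net charge by ``6 n``.  A single lysine linker between the globular
domain and the first repeat adds +1 and is used to build charge-equivalent
fusions from domains whose charges differ by less than one repeat.

Design rules encoded by :func:`design_tag`: a fusion net charge of exactly +6
sits at the intracellular phase-separation threshold and yields *transient*
condensates (they assemble during growth and disassemble again), while a net
charge of at least +12 yields *persistent* condensates.
"""

from __future__ import annotations

import csv
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

from Bio import SeqIO

from .errors import EmptyInputError, InfeasibleDesignError, InvalidResidueError

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Side-chain charge at neutral pH (H treated as neutral; termini ignored).
RESIDUE_CHARGES = {aa: 0 for aa in CANONICAL_RESIDUES}
RESIDUE_CHARGES.update({"K": +1, "R": +1, "D": -1, "E": -1})

#: The cationic tag repeat unit; each repeat contributes +6.
TAG_UNIT = "GGSKKRKKR"

#: Charge added per tag repeat.
TAG_UNIT_CHARGE = sum(RESIDUE_CHARGES[aa] for aa in TAG_UNIT)

BehaviorClass = Literal["none", "transient", "persistent"]


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence over the canonical 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyInputError(f"sequence {self.id!r} is empty")
        for pos, aa in enumerate(self.residues):
            if aa not in CANONICAL_RESIDUES:
                raise InvalidResidueError(aa, pos, self.id)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ChargeProfile:
    """Per-residue and net charge of a sequence.

    ``net_charge`` always equals ``sum(per_residue_charges)``.
    """

    sequence_id: str
    net_charge: int
    per_residue_charges: tuple[int, ...]


@dataclass(frozen=True)
class TagDesign:
    """A cationic-tag design for one globular domain.

    ``predicted_fusion_charge = domain_charge + linker_lysines + 6 * n_repeats``.
    ``fusion_peptide`` is the full designed sequence (domain residues, then the
    lysine linker, then the tag repeats) when the domain sequence is known, or
    just the appended peptide when only the domain charge was given.
    """

    domain_id: str
    domain_charge: int
    n_repeats: int
    linker_lysines: int
    predicted_fusion_charge: int
    behavior_class: BehaviorClass
    fusion_peptide: str

    @property
    def tag_peptide(self) -> str:
        """The appended peptide alone: linker lysines followed by the repeats."""
        return "K" * self.linker_lysines + TAG_UNIT * self.n_repeats


def residue_charge(aa: str) -> int:
    """Integer side-chain charge of one amino-acid letter.

    +1 for K/R, -1 for D/E, 0 otherwise.  Raises
    :class:`~phasetag.errors.InvalidResidueError` for non-canonical letters.
    """
    if len(aa) != 1 or aa not in CANONICAL_RESIDUES:
        raise InvalidResidueError(aa, 0)
    return RESIDUE_CHARGES[aa]


def _as_residues(seq: Union[ProteinSequence, str]) -> tuple[str, str]:
    if isinstance(seq, ProteinSequence):
        return seq.id, seq.residues
    return "", seq


def net_charge(seq: Union[ProteinSequence, str], *, permissive: bool = False) -> int:
    """Net charge of a sequence: sum of residue charges.

    Additive over concatenation by construction.  With ``permissive=True``
    non-canonical letters (X, B, Z, U, ...) count as neutral and are warned
    about instead of raising.
    """
    seq_id, residues = _as_residues(seq)
    if not residues:
        raise EmptyInputError("cannot compute the net charge of an empty sequence")
    total = 0
    for pos, aa in enumerate(residues):
        try:
            total += RESIDUE_CHARGES[aa]
        except KeyError:
            if not permissive:
                raise InvalidResidueError(aa, pos, seq_id) from None
            logger.warning(
                "non-canonical residue %r at position %d%s treated as neutral",
                aa, pos, f" in {seq_id!r}" if seq_id else "",
            )
    return total


def charge_profile(seq: Union[ProteinSequence, str]) -> ChargeProfile:
    """Per-residue charges plus their sum for one sequence."""
    seq_id, residues = _as_residues(seq)
    if not residues:
        raise EmptyInputError("cannot profile an empty sequence")
    per = tuple(residue_charge(aa) for aa in residues)
    return ChargeProfile(seq_id, sum(per), per)


def fusion_charge(domain_charge: int, n_repeats: int, linker_lysines: int = 0) -> int:
    """Net charge of domain + lysine linker + ``n`` tag repeats.

    ``domain_charge + linker_lysines + 6 * n_repeats``; repeat and linker
    counts must be non-negative.
    """
    if n_repeats < 0 or linker_lysines < 0:
        raise ValueError(
            f"repeat and linker counts must be >= 0, "
            f"got n_repeats={n_repeats}, linker_lysines={linker_lysines}"
        )
    return domain_charge + linker_lysines + TAG_UNIT_CHARGE * n_repeats


TRANSIENT_TARGET = 6  # fusion charge at the phase-separation threshold
PERSISTENT_TARGET = 12  # smallest charge observed to give persistent condensates


def design_tag(
    domain: Union[ProteinSequence, str, int],
    mode: Literal["transient", "persistent"],
    persistent_target: int = PERSISTENT_TARGET,
    max_linker_lysines: int = 5,
) -> TagDesign:
    """Choose the shortest cationic tag that meets a condensate-behavior goal.

    Parameters
    ----------
    domain
        The globular domain as a sequence (its charge is computed) or directly
        as an integer net charge.
    mode
        ``"transient"`` targets a fusion charge of exactly +6 (condensates form
        then disassemble during growth); ``"persistent"`` targets the smallest
        achievable fusion charge >= ``persistent_target``.
    persistent_target
        Minimum fusion charge for persistent condensates; must exceed +6.
    max_linker_lysines
        Upper bound on the lysine linker used to fine-tune the charge.

    Returns
    -------
    TagDesign
        Repeat count minimized first, then linker lysines; the emitted fusion
        peptide round-trips through :func:`net_charge` to the predicted charge.

    Raises
    ------
    InfeasibleDesignError
        In transient mode when the domain charge already exceeds +6 (repeats
        and linkers only add positive charge).
    """
    if mode not in ("transient", "persistent"):
        raise ValueError(f"mode must be 'transient' or 'persistent', got {mode!r}")
    if mode == "persistent" and persistent_target <= TRANSIENT_TARGET:
        raise ValueError(f"persistent_target must exceed +6, got {persistent_target}")

    if isinstance(domain, int):
        domain_id, domain_residues, dc = f"domain({domain:+d})", "", domain
    else:
        domain_id, domain_residues = _as_residues(domain)
        dc = net_charge(domain)

    unit = TAG_UNIT_CHARGE
    if mode == "transient":
        if dc > TRANSIENT_TARGET:
            raise InfeasibleDesignError(
                f"domain charge {dc:+d} exceeds +6; cationic repeats and "
                "linkers only add charge, so a +6 fusion is unreachable"
            )
        # smallest n with 0 <= 6 - dc - 6n <= max_linker_lysines
        deficit = TRANSIENT_TARGET - dc
        n = max(0, -(-(deficit - max_linker_lysines) // unit))
        linker = deficit - unit * n
        if linker < 0 or linker > max_linker_lysines:
            raise InfeasibleDesignError(
                f"no (repeats, linker<= {max_linker_lysines}) combination "
                f"reaches exactly +6 from domain charge {dc:+d}"
            )
        behavior: BehaviorClass = "transient"
    else:
        # smallest achievable value >= target, then smallest n, then linker
        best = None
        n_min = max(0, -(-(persistent_target - dc - max_linker_lysines) // unit))
        for n in range(n_min, n_min + 2):
            for linker in range(0, max_linker_lysines + 1):
                value = dc + linker + unit * n
                if value >= persistent_target:
                    key = (value, n, linker)
                    if best is None or key < best:
                        best = key
        assert best is not None
        _, n, linker = best
        behavior = "persistent"

    predicted = fusion_charge(dc, n, linker)
    peptide = domain_residues + "K" * linker + TAG_UNIT * n
    return TagDesign(
        domain_id=domain_id,
        domain_charge=dc,
        n_repeats=n,
        linker_lysines=linker,
        predicted_fusion_charge=predicted,
        behavior_class=behavior,
        fusion_peptide=peptide,
    )


@dataclass
class ChargeDistribution:
    """Empirical distribution of per-protein net charges across a proteome."""

    charges: list[int]
    n_skipped: int = 0
    _sorted: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.charges:
            raise EmptyInputError("charge distribution needs at least one entry")
        self._sorted = sorted(self.charges)

    def __len__(self) -> int:
        return len(self.charges)

    def cdf(self, charge: float) -> float:
        """Fraction of entries with net charge <= ``charge``."""
        return bisect_right(self._sorted, charge) / len(self._sorted)

    def fraction_in_window(self, lo: float, hi: float) -> float:
        """Fraction of entries with ``lo <= charge <= hi`` (inclusive)."""
        if lo > hi:
            raise ValueError(f"window lower bound {lo} exceeds upper bound {hi}")
        n = len(self._sorted)
        return (bisect_right(self._sorted, hi) - bisect_right(self._sorted, lo - 1e-9)) / n

    def cdf_table(self) -> list[tuple[int, float]]:
        """(charge, cumulative fraction) at each distinct charge, non-decreasing."""
        table = []
        n = len(self._sorted)
        for q in sorted(set(self._sorted)):
            table.append((q, bisect_right(self._sorted, q) / n))
        return table


def proteome_charge_distribution(
    records: Iterable[Union[ProteinSequence, str]],
    *,
    permissive: bool = True,
) -> ChargeDistribution:
    """Net-charge distribution over a collection of protein sequences.

    Invalid records are skipped with a warning and counted in ``n_skipped``
    (proteome FASTA files routinely contain X/B/Z placeholders; with
    ``permissive=True`` those residues count as neutral instead of voiding the
    whole record).
    """
    charges: list[int] = []
    skipped = 0
    for rec in records:
        try:
            charges.append(net_charge(rec, permissive=permissive))
        except (InvalidResidueError, EmptyInputError) as exc:
            skipped += 1
            logger.warning("skipping record: %s", exc)
    if not charges:
        raise EmptyInputError("no valid sequences in input")
    return ChargeDistribution(charges=charges, n_skipped=skipped)


def read_fasta(path: Union[str, Path], *, permissive: bool = True) -> list[ProteinSequence]:
    """Read a multi-record protein FASTA (wrapped lines, '>' headers).

    With ``permissive=True`` records containing non-canonical letters are kept
    (the charge functions treat those letters as neutral when asked to); with
    ``permissive=False`` such records raise.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace("-", "").replace("*", "")
        if not residues:
            logger.warning("skipping empty FASTA record %r", rec.id)
            continue
        if permissive:
            out.append(_PermissiveSequence(rec.id, residues))
        else:
            out.append(ProteinSequence(rec.id, residues))
    if not out:
        raise EmptyInputError(f"no sequences found in {path}")
    return out


class _PermissiveSequence(ProteinSequence):
    """A ProteinSequence that tolerates non-canonical letters (X, B, Z, U...)."""

    def __post_init__(self) -> None:  # noqa: D105
        if not self.residues:
            raise EmptyInputError(f"sequence {self.id!r} is empty")


def write_charge_table(
    records: Sequence[Union[ProteinSequence, str]],
    path: Union[str, Path],
    *,
    permissive: bool = True,
) -> None:
    """Write a CSV of (id, length, net_charge), one row per sequence."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "length", "net_charge"])
        for rec in records:
            seq_id, residues = _as_residues(rec)
            writer.writerow([seq_id, len(residues), net_charge(rec, permissive=permissive)])
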