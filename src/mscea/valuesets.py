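"""EQ-5D-3L value sets: mapping the 243 five-digit health-state codes to utilities.

An EQ-5D-3L response is a five-character code, one digit per dimension
(mobility, self-care, usual activities, pain/discomfort, anxiety/depression),
each scored 1 (no problems) to 3 (extreme problems).  A value set converts a
code into a single utility anchored at 1.0 for full health ("11111"); scores
below zero denote states judged worse than death.

Value sets are country-specific preference weights and are pluggable here.
The package bundles a *synthetic* additive value set (decrement per
dimension-level, floor -0.2) for testing the scoring path; it is not any
published tariff.  User value sets load from either a full 243-row code/score
table or a dimension/level coefficient file.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

EQ5D_DIMENSIONS = ("MO", "SC", "UA", "PD", "AD")
N_CODES = 3 ** 5  # 243


class ValueSetError(ValueError):
    """Malformed EQ-5D code or inconsistent value-set definition."""


def validate_code(code: str) -> str:
    """Check that ``code`` is a valid EQ-5D-3L response ("^[123]{5}$")."""
    if not isinstance(code, str) or len(code) != 5:
        raise ValueSetError(
            f"EQ-5D-3L code must be a 5-character string, got {code!r}"
        )
    for pos, ch in enumerate(code):
        if ch not in "123":
            raise ValueSetError(
                f"invalid EQ-5D-3L digit {ch!r} at position {pos + 1} "
                f"(dimension {EQ5D_DIMENSIONS[pos]}) in code {code!r}; "
                "levels are 1-3"
            )
    return code


def all_codes() -> list[str]:
    """All 243 EQ-5D-3L codes in lexicographic order."""
    return ["".join(d) for d in itertools.product("123", repeat=5)]


@dataclass(frozen=True)
class ValueSet:
    """A complete EQ-5D-3L scoring function.

    Parameters
    ----------
    name
        Label used in reports.
    scores
        Mapping of every one of the 243 codes to a utility <= 1, with
        ``scores["11111"] == 1.0``.
    """

    name: str
    scores: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(all_codes()) - set(self.scores)
        if missing:
            raise ValueSetError(
                f"value set {self.name!r} is incomplete: "
                f"{len(missing)} codes unresolvable (e.g. {sorted(missing)[:3]})"
            )
        if abs(self.scores["11111"] - 1.0) > 1e-12:
            raise ValueSetError(
                f"value set {self.name!r}: score('11111') must be 1.0, "
                f"got {self.scores['11111']}"
            )
        bad = [c for c, s in self.scores.items() if s > 1.0 + 1e-12]
        if bad:
            raise ValueSetError(
                f"value set {self.name!r}: scores above 1.0 for codes {bad[:3]}"
            )

    def score(self, code: str) -> float:
        validate_code(code)
        return self.scores[code]

    @property
    def min_score(self) -> float:
        return min(self.scores.values())

    @property
    def max_score(self) -> float:
        return max(self.scores.values())

    # ------------------------------------------------------------------ io

    @classmethod
    def from_coefficients(
        cls, decrements: dict[str, dict[int, float]], name: str
    ) -> "ValueSet":
        """Build an additive value set from per-dimension level decrements.

        ``decrements[dim][level]`` is subtracted from 1.0 for each dimension
        at level 2 or 3; level 1 carries no decrement.
        """
        for dim in EQ5D_DIMENSIONS:
            if dim not in decrements:
                raise ValueSetError(f"coefficient set missing dimension {dim!r}")
            for level in (2, 3):
                if level not in decrements[dim]:
                    raise ValueSetError(
                        f"coefficient set missing level {level} for dimension {dim!r}"
                    )
        scores: dict[str, float] = {}
        for code in all_codes():
            dec = 0.0
            for dim, ch in zip(EQ5D_DIMENSIONS, code):
                level = int(ch)
                if level > 1:
                    dec += decrements[dim][level]
            scores[code] = 1.0 - dec
        return cls(name=name, scores=scores)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "ValueSet":
        """Load a value set from a delimited text file.

        Two layouts are accepted (tab- or whitespace-delimited, ``#`` comments):

        * code table — two columns ``code  score``, 243 rows;
        * coefficient table — three columns ``dimension  level  decrement``
          for each of the five dimensions at levels 2 and 3.
        """
        path = Path(path)
        label = name or path.stem
        code_rows: dict[str, float] = {}
        coef_rows: dict[str, dict[int, float]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) == 2:
                    code, score = parts
                    validate_code(code)
                    code_rows[code] = float(score)
                elif len(parts) == 3:
                    dim, level, dec = parts
                    if dim not in EQ5D_DIMENSIONS:
                        raise ValueSetError(
                            f"{path}:{lineno}: unknown dimension {dim!r}"
                        )
                    coef_rows.setdefault(dim, {})[int(level)] = float(dec)
                else:
                    raise ValueSetError(
                        f"{path}:{lineno}: expected 2 (code, score) or "
                        f"3 (dimension, level, decrement) columns, got {len(parts)}"
                    )
        if code_rows and coef_rows:
            raise ValueSetError(f"{path}: mixes code-table and coefficient rows")
        if coef_rows:
            return cls.from_coefficients(coef_rows, name=label)
        return cls(name=label, scores=code_rows)

    def to_file(self, path: str | Path) -> None:
        """Write the full 243-code score table."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# EQ-5D-3L value set: {self.name}\n# code\tscore\n")
            for code in all_codes():
                fh.write(f"{code}\t{self.scores[code]!r}\n")


def synthetic_reference() -> ValueSet:
    """The bundled synthetic test value set (additive, floor -0.2).

    This is a stand-in scoring function for exercising the utility pipeline;
    its coefficients are invented and match no published national tariff.
    """
    ref = resources.files("mscea.data") / "synthetic_valueset.tsv"
    with resources.as_file(ref) as path:
        return ValueSet.from_file(path, name="synthetic-test-valueset")
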