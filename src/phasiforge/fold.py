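"""RNA secondary-structure backends.

The default backend is the ViennaRNA thermodynamic MFE engine (``import
RNA``).  A simple Nussinov base-pair-maximisation backend is bundled for
structure-only work (its "energy" is the negated pair count, not kcal/mol,
so thermodynamic filters are meaningless with it); it exists so structural
logic can be exercised without the thermodynamic engine.
"""

from __future__ import annotations

from typing import Protocol

try:  # ViennaRNA python bindings (shipped with the ViennaRNA distribution)
    import RNA as _RNA
except ImportError:  # pragma: no cover - environment without ViennaRNA
    _RNA = None

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


class FoldBackend(Protocol):
    def fold(self, seq: str) -> tuple[str, float]:
        """Return (dot-bracket structure, minimum free energy)."""


class ViennaBackend:
    """Thermodynamic MFE folding via the ViennaRNA bindings."""

    def __init__(self) -> None:
        if _RNA is None:  # pragma: no cover
            raise ImportError("ViennaRNA python bindings (module 'RNA') are not available")

    def fold(self, seq: str) -> tuple[str, float]:
        structure, mfe = _RNA.fold(seq.replace("T", "U"))
        return structure, float(mfe)


class NussinovBackend:
    """Base-pair maximisation (Nussinov DP) with canonical + G:U pairs.

    Returns the negated maximal pair count as the energy surrogate.
    Minimum hairpin loop size 3, matching the thermodynamic convention.
    """

    def __init__(self, min_loop: int = 3):
        self.min_loop = min_loop

    def fold(self, seq: str) -> tuple[str, float]:
        n = len(seq)
        h = self.min_loop
        best = [[0] * n for _ in range(n)]
        for span in range(h + 1, n):
            for i in range(n - span):
                j = i + span
                b = best[i][j - 1]
                for k in range(i, j - h):
                    if (seq[k], seq[j]) in _PAIRS:
                        left = best[i][k - 1] if k > i else 0
                        cand = left + 1 + best[k + 1][j - 1]
                        if cand > b:
                            b = cand
                best[i][j] = b
        structure = ["."] * n

        def backtrack(i: int, j: int) -> None:
            while j > i + h:
                if best[i][j] == best[i][j - 1]:
                    j -= 1
                    continue
                for k in range(i, j - h):
                    if (seq[k], seq[j]) in _PAIRS:
                        left = best[i][k - 1] if k > i else 0
                        if left + 1 + best[k + 1][j - 1] == best[i][j]:
                            structure[k] = "("
                            structure[j] = ")"
                            if k > i:
                                backtrack(i, k - 1)
                            i, j = k + 1, j - 1
                            break
                else:  # pragma: no cover - defensive
                    break

        if n:
            backtrack(0, n - 1)
        return "".join(structure), -float(best[0][n - 1] if n else 0)


def default_backend() -> FoldBackend:
    if _RNA is not None:
        return ViennaBackend()
    return NussinovBackend()  # pragma: no cover


def pair_table(structure: str) -> list[int]:
    """0-based pair table: pt[i] = partner of i, or -1 if unpaired."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt
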