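"""Intermolecular miRNA:target duplex minimum free energy by dynamic programming.

Hybridization-only model: the two strands pair antiparallel through
Watson-Crick and G:U wobble pairs; consecutive pairs contribute
nearest-neighbor stacking energies, and interruptions cost affine bulge
(one-sided) or internal-loop (two-sided) penalties.  No intramolecular
structure is considered and dangling ends are free, so the reported MFE is
the energy of the best duplex alone (RNAhybrid-style).  If no duplex has
negative energy the MFE is 0 with an empty pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

__all__ = ["EnergyModel", "DuplexResult", "load_energy_model", "duplex_mfe",
           "binding_start", "pairing_string"]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_LEGAL_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}
MAX_TARGET_LEN = 60
_MAX_LOOP = 15  # unpaired run per strand inside the duplex


@dataclass
class EnergyModel:
    stack: dict[tuple[str, str], float]
    duplex_init: float
    bulge_open: float
    bulge_extend: float
    internal_open: float
    internal_extend: float

    def __post_init__(self) -> None:
        if any(e >= 0 for e in self.stack.values()):
            raise ValueError("all stack energies must be negative")
        for name in ("bulge_open", "bulge_extend", "internal_open",
                     "internal_extend"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for (p1, p2), e in self.stack.items():
            mirror = (p2[::-1], p1[::-1])
            if abs(self.stack.get(mirror, float("nan")) - e) > 1e-9:
                raise ValueError(f"stack table not strand-exchange symmetric "
                                 f"at {p1}/{p2}")

    def loop_energy(self, a: int, b: int) -> float:
        """Cost of a unpaired nt on one strand and b on the other."""
        if a == 0 and b == 0:
            raise ValueError("use the stack table for adjacent pairs")
        if a == 0 or b == 0:
            size = a + b
            return self.bulge_open + self.bulge_extend * (size - 1)
        return self.internal_open + self.internal_extend * (a + b - 2)


@dataclass
class DuplexResult:
    mfe: float
    # (miRNA position, target position), 1-based, miRNA ascending 5'->3',
    # target descending (antiparallel)
    pairing: list[tuple[int, int]] = field(default_factory=list)

    @property
    def binding_start(self) -> int:
        return binding_start(self)


def load_energy_model(path=None) -> EnergyModel:
    """Read the packaged (or a caller-supplied) plain-text parameter file."""
    if path is None:
        text = (resources.files("perimir") / "data" / "stack_energies.tsv") \
            .read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    stack: dict[tuple[str, str], float] = {}
    params: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, *rest = line.split("\t")
        if kind == "stack":
            p1, p2, e = rest
            stack[(p1, p2)] = float(e)
        elif kind == "param":
            name, v = rest
            params[name] = float(v)
        else:
            raise ValueError(f"unrecognized record {kind!r}")
    return EnergyModel(stack=stack, **params)


_DEFAULT_MODEL: EnergyModel | None = None


def default_energy_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_energy_model()
    return _DEFAULT_MODEL


def _validate(seq: str, what: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-RNA characters in {what}: {sorted(bad)}")
    return seq


def duplex_mfe(mirna: str, target_region: str,
               model: EnergyModel | None = None) -> DuplexResult:
    """Global minimum-free-energy intermolecular duplex.

    ``target_region`` is the (short, <= 60 nt) stretch of target mRNA around
    a candidate site; full-length-UTR folding is out of scope by design.
    """
    model = model or default_energy_model()
    a = _validate(mirna, "miRNA")
    b = _validate(target_region, "target")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both sequences must have length >= 2")
    if len(b) > MAX_TARGET_LEN:
        raise ValueError(f"target region longer than {MAX_TARGET_LEN} nt")
    # align miRNA (5'->3') against the reversed target so both indices ascend
    br = b[::-1]
    m, t = len(a), len(br)

    def pair(i: int, k: int) -> str | None:
        p = a[i] + br[k]
        return p if p in _LEGAL_PAIRS else None

    INF = float("inf")
    # best[i][k]: min energy of a duplex whose 3'-most (on miRNA) pair is (i,k)
    best = [[INF] * t for _ in range(m)]
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    order: list[tuple[int, int]] = []
    for i in range(m):
        for k in range(t):
            p = pair(i, k)
            if p is None:
                continue
            e = model.duplex_init
            parent: tuple[int, int] | None = None
            for ip in range(max(0, i - _MAX_LOOP - 1), i):
                for kp in range(max(0, k - _MAX_LOOP - 1), k):
                    if best[ip][kp] == INF:
                        continue
                    ga, gb = i - ip - 1, k - kp - 1
                    if ga == 0 and gb == 0:
                        step = model.stack[(pair(ip, kp), p)]
                    else:
                        step = model.loop_energy(ga, gb)
                    cand = best[ip][kp] + step
                    if cand < e:
                        e = cand
                        parent = (ip, kp)
            best[i][k] = e
            back[(i, k)] = parent
            order.append((i, k))
    if not order:
        return DuplexResult(mfe=0.0)
    end = min(order, key=lambda ik: best[ik[0]][ik[1]])
    mfe = best[end[0]][end[1]]
    if mfe >= 0:
        return DuplexResult(mfe=0.0)
    # traceback
    chain: list[tuple[int, int]] = []
    node: tuple[int, int] | None = end
    while node is not None:
        chain.append(node)
        node = back[node]
    chain.reverse()
    pairing = [(i + 1, len(b) - k) for i, k in chain]
    return DuplexResult(mfe=float(mfe), pairing=pairing)


def binding_start(result: DuplexResult) -> int:
    """5'-most miRNA nucleotide participating in the optimal duplex (1-based)."""
    if not result.pairing:
        raise ValueError("empty pairing has no binding start")
    return min(i for i, _ in result.pairing)


def pairing_string(mirna: str, target_region: str,
                   result: DuplexResult) -> str:
    """Two-line dot-bracket-like rendering of a duplex trace."""
    mi = ["."] * len(mirna)
    tg = ["."] * len(target_region)
    for i, j in result.pairing:
        mi[i - 1] = "("
        tg[j - 1] = ")"
    return f"5'{''.join(mi)}3' miRNA\n3'{''.join(tg)[::-1]}5' target"
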