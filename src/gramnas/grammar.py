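"""BNF grammar parsing and integer-codon genotype-to-phenotype mapping.

The genotype is a fixed-capacity vector of integer codons.  Decoding
repeatedly expands the left-most nonterminal of a context-free grammar,
choosing the production ``codon mod n_alternatives``; the resulting terminal
sentence is assembled into a :class:`TopologySpec`.  Codons are consumed only
at genuine choice points (rules with more than one alternative) unless
``consume_single`` is set.  There is no codon wrapping: a derivation that
exhausts its chromosome is returned as incomplete.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GrammarError",
    "GrammarDef",
    "Chromosome",
    "ConvLayerSpec",
    "DenseLayerSpec",
    "TopologySpec",
    "DerivationNode",
    "DerivationResult",
    "parse_grammar",
    "load_default_grammar",
    "decode",
    "random_chromosome",
    "phenotype_to_text",
    "phenotype_from_text",
]

_NT_RE = re.compile(r"^<[^<>\s]+>$")
_RULE_RE = re.compile(r"^\s*(<[^<>\s]+>)\s*::=\s*(.+)$")

ACTIVATIONS = ("linear", "ReLU")
DENSE_TYPES = ("feedforward", "LSTM", "GRU")
REGULARIZERS = ("none", "L1", "L2")
OPTIMIZERS = ("SGD", "AdaGrad", "AdaDelta", "RMSProp", "Adam", "Adamax")

# lower-case grammar terminals -> canonical display names
_CANON = {s.lower(): s for s in ACTIVATIONS + DENSE_TYPES + REGULARIZERS + OPTIMIZERS}


class GrammarError(ValueError):
    """Raised for malformed or inconsistent grammar text."""


def _is_nonterminal(token: str) -> bool:
    return _NT_RE.match(token) is not None


@dataclass(frozen=True)
class GrammarDef:
    """An ordered set of BNF rules plus a start symbol."""

    rules: Mapping[str, tuple[tuple[str, ...], ...]]
    start_symbol: str

    def __post_init__(self) -> None:
        if self.start_symbol not in self.rules:
            raise GrammarError(f"start symbol {self.start_symbol} has no rule")
        for nt, productions in self.rules.items():
            if not productions:
                raise GrammarError(f"rule {nt} has no productions")
            for prod in productions:
                for token in prod:
                    if _is_nonterminal(token) and token not in self.rules:
                        raise GrammarError(
                            f"undefined nonterminal {token} referenced in rule {nt}"
                        )

    def alternatives(self, nonterminal: str) -> tuple[tuple[str, ...], ...]:
        return self.rules[nonterminal]

    def to_text(self) -> str:
        lines = []
        for nt, productions in self.rules.items():
            alts = " | ".join(" ".join(prod) for prod in productions)
            lines.append(f"{nt} ::= {alts}")
        return "\n".join(lines) + "\n"


def parse_grammar(bnf_text: str) -> GrammarDef:
    """Parse plain-text BNF (one rule per line, ``|``-separated alternatives).

    The start symbol is the left-hand side of the first rule.  Raises
    :class:`GrammarError` on a malformed line or a reference to an undefined
    nonterminal.
    """
    rules: dict[str, tuple[tuple[str, ...], ...]] = {}
    start: str | None = None
    for lineno, raw in enumerate(bnf_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _RULE_RE.match(line)
        if m is None:
            raise GrammarError(f"malformed rule on line {lineno}: {raw!r}")
        nt, rhs = m.group(1), m.group(2)
        if nt in rules:
            raise GrammarError(f"duplicate rule for {nt} on line {lineno}")
        productions = []
        for alt in rhs.split("|"):
            tokens = tuple(alt.split())
            if not tokens:
                raise GrammarError(f"empty alternative in rule {nt} on line {lineno}")
            productions.append(tokens)
        rules[nt] = tuple(productions)
        if start is None:
            start = nt
    if start is None:
        raise GrammarError("grammar contains no rules")
    return GrammarDef(rules=rules, start_symbol=start)


def load_default_grammar() -> GrammarDef:
    """Load the network-topology grammar shipped with the package."""
    text = resources.files("gramnas.data").joinpath("network.bnf").read_text()
    return parse_grammar(text)


@dataclass(frozen=True)
class Chromosome:
    """Fixed-capacity vector of integer codons in ``[0, codon_size)``."""

    codons: tuple[int, ...]
    codon_size: int = 256
    capacity: int = 100

    def __post_init__(self) -> None:
        if self.codon_size < 2:
            raise ValueError("codon_size must be >= 2")
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        if len(self.codons) > self.capacity:
            raise ValueError("chromosome exceeds capacity")
        if any(c < 0 or c >= self.codon_size for c in self.codons):
            raise ValueError("codon out of range")

    def __len__(self) -> int:
        return len(self.codons)


def random_chromosome(
    codon_size: int, capacity: int, rng: np.random.Generator
) -> Chromosome:
    """Draw ``capacity`` codons uniformly from ``[0, codon_size)``."""
    if codon_size < 2:
        raise ValueError("codon_size must be >= 2")
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    codons = tuple(int(c) for c in rng.integers(0, codon_size, size=capacity))
    return Chromosome(codons=codons, codon_size=codon_size, capacity=capacity)


@dataclass(frozen=True)
class ConvLayerSpec:
    kernels: int          # ck
    kernel_size: int      # cs
    pooling: int          # cp, 1 = no pooling
    activation: str       # ca

    def __post_init__(self) -> None:
        if self.kernels < 1:
            raise ValueError("kernels must be >= 1")
        if self.kernel_size < 2:
            raise ValueError("kernel_size must be >= 2")
        if self.pooling < 1:
            raise ValueError("pooling must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation}")


@dataclass(frozen=True)
class DenseLayerSpec:
    layer_type: str       # dt
    units: int            # dn
    dropout: float        # dd
    activation: str       # da
    regularizer: str      # dr

    def __post_init__(self) -> None:
        if self.layer_type not in DENSE_TYPES:
            raise ValueError(f"unknown dense layer type {self.layer_type}")
        if self.units < 1:
            raise ValueError("units must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation}")
        if self.regularizer not in REGULARIZERS:
            raise ValueError(f"unknown regularizer {self.regularizer}")


@dataclass(frozen=True)
class TopologySpec:
    """Decoded phenotype: input setup, layer stack, and learning setup."""

    batch_size: int       # B
    window_size: int      # w
    window_step: int      # wstep
    conv_layers: tuple[ConvLayerSpec, ...]
    dense_layers: tuple[DenseLayerSpec, ...]
    optimizer: str        # f
    learning_rate: float  # eta

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.window_size < 1 or self.window_step < 1:
            raise ValueError("input setup values must be >= 1")
        if not self.conv_layers:
            raise ValueError("at least one conv layer required")
        if not self.dense_layers:
            raise ValueError("at least one dense layer required")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer}")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    @property
    def n_conv(self) -> int:
        return len(self.conv_layers)

    @property
    def n_dense(self) -> int:
        return len(self.dense_layers)

    def slots(self) -> tuple:
        """Positionally aligned hyperparameter slots, used by the niching
        similarity measure: input setup, conv fields in order, dense fields
        in order, learning setup."""
        out: list = [self.batch_size, self.window_size, self.window_step]
        for c in self.conv_layers:
            out.extend((c.kernels, c.kernel_size, c.pooling, c.activation))
        for d in self.dense_layers:
            out.extend((d.layer_type, d.units, d.dropout, d.activation, d.regularizer))
        out.extend((self.optimizer, self.learning_rate))
        return tuple(out)


@dataclass
class DerivationNode:
    """One nonterminal expansion in the derivation tree."""

    symbol: str
    production_index: int
    children: list["DerivationNode | str"] = field(default_factory=list)


@dataclass(frozen=True)
class DerivationResult:
    phenotype: TopologySpec | None
    codons_used: int
    tree: DerivationNode | None
    complete: bool


def _fmt_number(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return repr(x)


def _parse_value(token: str):
    if token in _CANON:
        return _CANON[token]
    try:
        f = float(token)
    except ValueError as exc:
        raise GrammarError(f"unexpected terminal {token!r}") from exc
    return int(f) if f == int(f) else f


def _assemble(sentence: Sequence[str]) -> TopologySpec:
    """Build a TopologySpec from the terminal sentence of the grammar.

    The sentence protocol is keyword-framed:
    ``batch B window w step ws (conv ck cs cp ca)+ (dense dt dn dd da dr)+
    optimizer f rate eta``.  Custom grammars must emit this protocol.
    """
    it: Iterator[str] = iter(sentence)

    def expect(keyword: str) -> None:
        tok = next(it)
        if tok != keyword:
            raise GrammarError(f"expected {keyword!r} in sentence, got {tok!r}")

    def value():
        return _parse_value(next(it))

    expect("batch")
    batch = value()
    expect("window")
    window = value()
    expect("step")
    step = value()

    conv_layers: list[ConvLayerSpec] = []
    dense_layers: list[DenseLayerSpec] = []
    tok = next(it)
    while tok == "conv":
        conv_layers.append(
            ConvLayerSpec(
                kernels=int(value()),
                kernel_size=int(value()),
                pooling=int(value()),
                activation=value(),
            )
        )
        tok = next(it)
    while tok == "dense":
        dense_layers.append(
            DenseLayerSpec(
                layer_type=value(),
                units=int(value()),
                dropout=float(value()),
                activation=value(),
                regularizer=value(),
            )
        )
        tok = next(it)
    if tok != "optimizer":
        raise GrammarError(f"expected 'optimizer' in sentence, got {tok!r}")
    optimizer = value()
    expect("rate")
    eta = float(value())

    return TopologySpec(
        batch_size=int(batch),
        window_size=int(window),
        window_step=int(step),
        conv_layers=tuple(conv_layers),
        dense_layers=tuple(dense_layers),
        optimizer=optimizer,
        learning_rate=eta,
    )


def decode(
    chromosome: Chromosome,
    grammar: GrammarDef,
    *,
    consume_single: bool = False,
    assemble: bool = True,
) -> DerivationResult:
    """Map a chromosome to a phenotype via left-most grammar expansion.

    Production choice at each nonterminal with ``n`` alternatives is
    ``codon mod n``; a codon is consumed only when ``n > 1`` (or always, with
    ``consume_single``).  If codons run out before the derivation terminates
    the result is incomplete and carries no phenotype.

    With ``assemble=False`` the terminal sentence is not converted to a
    :class:`TopologySpec` (useful for toy grammars); the sentence is then
    attached to the tree only.
    """
    codons = chromosome.codons
    pos = 0
    root = DerivationNode(symbol=grammar.start_symbol, production_index=-1)
    # stack of (node, pending-symbol-list) frames; leftmost-first expansion
    sentence: list[str] = []
    stack: list[DerivationNode] = [root]
    while stack:
        node = stack.pop()
        alts = grammar.alternatives(node.symbol)
        if len(alts) > 1 or consume_single:
            if pos >= len(codons):
                return DerivationResult(
                    phenotype=None, codons_used=len(codons), tree=None, complete=False
                )
            choice = codons[pos] % len(alts)
            pos += 1
        else:
            choice = 0
        node.production_index = choice
        children: list[DerivationNode | str] = []
        pending: list[DerivationNode] = []
        for token in alts[choice]:
            if _is_nonterminal(token):
                child = DerivationNode(symbol=token, production_index=-1)
                children.append(child)
                pending.append(child)
            else:
                children.append(token)
        node.children = children
        # push pending nonterminals so the left-most is expanded first;
        # terminals between them are emitted in order via a final tree walk
        stack.extend(reversed(pending))

    def _walk(n: DerivationNode) -> None:
        for child in n.children:
            if isinstance(child, str):
                sentence.append(child)
            else:
                _walk(child)

    _walk(root)
    phenotype = _assemble(sentence) if assemble else None
    return DerivationResult(
        phenotype=phenotype, codons_used=pos, tree=root, complete=True
    )


def sentence_of(tree: DerivationNode) -> tuple[str, ...]:
    """Terminal sentence of a completed derivation tree."""
    out: list[str] = []

    def _walk(n: DerivationNode) -> None:
        for child in n.children:
            if isinstance(child, str):
                out.append(child)
            else:
                _walk(child)

    _walk(tree)
    return tuple(out)


def phenotype_to_text(spec: TopologySpec) -> str:
    """Render a spec in the per-layer symbol convention.

    Example: ``B=50 w=24 wstep=2 f=Adam eta=0.001 ck1=32 cs1=4 cp1=1
    ca1=ReLU dt1=LSTM dn1=512 dd1=0.5 da1=ReLU dr1=L2``.  Parses back to an
    equal spec via :func:`phenotype_from_text`.
    """
    parts = [
        f"B={spec.batch_size}",
        f"w={spec.window_size}",
        f"wstep={spec.window_step}",
        f"f={spec.optimizer}",
        f"eta={_fmt_number(spec.learning_rate)}",
    ]
    for i, c in enumerate(spec.conv_layers, start=1):
        parts.append(f"ck{i}={c.kernels}")
        parts.append(f"cs{i}={c.kernel_size}")
        parts.append(f"cp{i}={c.pooling}")
        parts.append(f"ca{i}={c.activation}")
    for i, d in enumerate(spec.dense_layers, start=1):
        parts.append(f"dt{i}={d.layer_type}")
        parts.append(f"dn{i}={d.units}")
        parts.append(f"dd{i}={_fmt_number(d.dropout)}")
        parts.append(f"da{i}={d.activation}")
        parts.append(f"dr{i}={d.regularizer}")
    return " ".join(parts)


def phenotype_from_text(text: str) -> TopologySpec:
    """Inverse of :func:`phenotype_to_text`."""
    kv: dict[str, str] = {}
    for part in text.split():
        if "=" not in part:
            raise GrammarError(f"malformed phenotype token {part!r}")
        k, v = part.split("=", 1)
        kv[k] = v

    def canon(v: str) -> str:
        return _CANON.get(v.lower(), v)

    conv_layers = []
    i = 1
    while f"ck{i}" in kv:
        conv_layers.append(
            ConvLayerSpec(
                kernels=int(kv[f"ck{i}"]),
                kernel_size=int(kv[f"cs{i}"]),
                pooling=int(kv[f"cp{i}"]),
                activation=canon(kv[f"ca{i}"]),
            )
        )
        i += 1
    dense_layers = []
    i = 1
    while f"dt{i}" in kv:
        dense_layers.append(
            DenseLayerSpec(
                layer_type=canon(kv[f"dt{i}"]),
                units=int(kv[f"dn{i}"]),
                dropout=float(kv[f"dd{i}"]),
                activation=canon(kv[f"da{i}"]),
                regularizer=canon(kv[f"dr{i}"]),
            )
        )
        i += 1
    return TopologySpec(
        batch_size=int(kv["B"]),
        window_size=int(kv["w"]),
        window_step=int(kv["wstep"]),
        conv_layers=tuple(conv_layers),
        dense_layers=tuple(dense_layers),
        optimizer=canon(kv["f"]),
        learning_rate=float(kv["eta"]),
    )
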