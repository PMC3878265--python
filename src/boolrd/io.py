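"""Reading and writing signed networks and binarized expression profiles.

Two network dialects:

``sif-signed``
    3 columns: source, sign token, target.  Sign tokens are ``->``
    (activation) and ``-|`` (inhibition); embedded spaces as printed in
    interaction tables (``- >``) are tolerated.

``tsv-3col``
    3 columns: source, target, sign, where sign is one of ``+``, ``-``,
    ``activation``, ``inhibition``, ``+1``, ``-1``.

Profiles are TSV with columns gene, initial, final (0/1 values; a header
row is detected and skipped).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Union

import pandas as pd

from .network import (
    ACTIVATION,
    INHIBITION,
    ExpressionProfilePair,
    NetworkFormatError,
    SignedNetwork,
)

_SIGN_WORDS = {
    "+": ACTIVATION,
    "-": INHIBITION,
    "+1": ACTIVATION,
    "-1": INHIBITION,
    "activation": ACTIVATION,
    "inhibition": INHIBITION,
    "activates": ACTIVATION,
    "inhibits": INHIBITION,
}


def _parse_sif_sign(token: str, path: str, lineno: int) -> int:
    compact = token.replace(" ", "")
    if compact == "->":
        return ACTIVATION
    if compact == "-|":
        return INHIBITION
    raise NetworkFormatError(
        f"{path}:{lineno}: unknown sign token {token!r} (expected '->' or '-|')"
    )


def normalize_mirna_name(name: str) -> str:
    """Uppercase and strip a leading 'hsa-' species prefix (miRNA tables)."""
    return re.sub(r"^hsa-", "", name, flags=re.IGNORECASE).upper()


def read_network(
    path: Union[str, Path],
    dialect: str = "sif-signed",
    normalize_names: bool = False,
) -> SignedNetwork:
    """Parse a signed network file; errors carry the offending line number."""
    path = Path(path)
    net = SignedNetwork()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 3:
                # tolerate whitespace-delimited files
                fields = line.split()
            if dialect == "sif-signed":
                if len(fields) == 4 and fields[1] + fields[2] in ("->", "-|"):
                    fields = [fields[0], fields[1] + fields[2], fields[3]]
                if len(fields) != 3:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: expected 3 columns (source, sign, target), "
                        f"got {len(fields)}"
                    )
                src, token, tgt = fields
                sign = _parse_sif_sign(token, str(path), lineno)
            elif dialect == "tsv-3col":
                if len(fields) != 3:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: expected 3 columns (source, target, sign), "
                        f"got {len(fields)}"
                    )
                src, tgt, token = fields
                try:
                    sign = _SIGN_WORDS[token.lower()]
                except KeyError:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: unknown sign {token!r}"
                    ) from None
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            if normalize_names:
                src, tgt = normalize_mirna_name(src), normalize_mirna_name(tgt)
            try:
                net.add_edge(src, tgt, sign)
            except NetworkFormatError as err:
                raise NetworkFormatError(f"{path}:{lineno}: {err}") from None
    return net


def write_network(
    network: SignedNetwork, path: Union[str, Path], dialect: str = "sif-signed"
) -> None:
    with open(path, "w") as fh:
        for u, v, s in network.edges:
            if dialect == "sif-signed":
                token = "->" if s == ACTIVATION else "-|"
                fh.write(f"{u}\t{token}\t{v}\n")
            elif dialect == "tsv-3col":
                fh.write(f"{u}\t{v}\t{'+' if s == ACTIVATION else '-'}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def read_profiles(path: Union[str, Path]) -> ExpressionProfilePair:
    """TSV (gene, initial, final) -> binarized profile pair."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise NetworkFormatError(f"{path}: expected 3 columns (gene, initial, final)")
    first = df.iloc[0]
    if str(first[1]).strip().isalpha() and str(first[2]).strip().isalpha():
        df = df.iloc[1:]  # header row ("gene  initial  final")
    if df.empty:
        raise NetworkFormatError(f"{path}: no profile rows")
    initial, final = {}, {}
    for _, row in df.iterrows():
        gene = str(row[0]).strip()
        values = []
        for cell in (row[1], row[2]):
            cell = str(cell).strip()
            if cell not in ("0", "1"):
                raise NetworkFormatError(
                    f"{path}: non-binary profile value {cell!r} for gene {gene!r}"
                )
            values.append(int(cell))
        initial[gene], final[gene] = values
    return ExpressionProfilePair(initial=initial, final=final)


def write_profiles(profiles: ExpressionProfilePair, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tinitial\tfinal\n")
        for g in profiles.measured:
            fh.write(f"{g}\t{profiles.initial[g]}\t{profiles.final[g]}\n")


def read_regulondb(
    path: Union[str, Path],
    ambiguous: str = "drop",
) -> SignedNetwork:
    """Parse a RegulonDB-style TF->gene table (regulator, target, effect).

    Effects ``+`` and ``-`` map to activation/inhibition; dual-sign ``+-``
    and unknown ``?`` rows are dropped by default (the Boolean model has no
    dual-sign edges) or coerced with ``ambiguous='activation'|'inhibition'``.
    Comment lines (#) and extra columns are ignored.
    """
    if ambiguous not in ("drop", "activation", "inhibition"):
        raise ValueError(f"unknown ambiguous-sign policy {ambiguous!r}")
    net = SignedNetwork()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in re.split(r"\t", line)]
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected >= 3 columns (regulator, target, effect)"
                )
            src, tgt, effect = fields[0], fields[1], fields[2]
            if effect == "+":
                sign = ACTIVATION
            elif effect == "-":
                sign = INHIBITION
            elif effect in ("+-", "-+", "?"):
                if ambiguous == "drop":
                    continue
                sign = ACTIVATION if ambiguous == "activation" else INHIBITION
            else:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unknown effect {effect!r}"
                )
            try:
                net.add_edge(src, tgt, sign)
            except NetworkFormatError:
                # conflicting annotations across rows behave like a dual sign
                if ambiguous == "drop":
                    continue
                raise
    return net
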