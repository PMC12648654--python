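"""Contracts for the external tools the suite orchestrates.

Protein coarse-graining (Martinize2), hydrogen/topology generation
(pdb2gmx), membrane embedding (MemPrO) and CG→AA back-mapping (CG2AT) run
as external programs.  Argument-list construction here is pure and
unit-testable; execution is injected so tests can mock it and offline runs
plan-and-skip with a clear notice.
"""

from __future__ import annotations

import logging
import os
import shutil
from dataclasses import dataclass, field

from .errors import ExternalToolError, UsageError

logger = logging.getLogger(__name__)

#: Environment variables the membrane-embedding pipeline requires.
MEMPRO_ENV_VARS = ("NUM_CPU", "PATH_TO_INSANE", "PATH_TO_MARTINI")


@dataclass(frozen=True)
class PlannedInvocation:
    tool: str
    argv: tuple[str, ...]


@dataclass
class InvocationLog:
    planned: list[PlannedInvocation] = field(default_factory=list)

    def record(self, tool: str, argv: list[str]) -> PlannedInvocation:
        inv = PlannedInvocation(tool=tool, argv=tuple(argv))
        self.planned.append(inv)
        logger.info("planned external invocation: %s %s", tool,
                    " ".join(argv))
        return inv


def plan_pdb2gmx(input_pdb: str, output_pdb: str,
                 extra_args: list[str] | None = None) -> list[str]:
    """Topology generation and hydrogen re-addition; extra args override
    all defaults."""
    if extra_args:
        return list(extra_args)
    return ["-f", input_pdb, "-o", output_pdb, "-water", "tip3p"]


def check_membrane_composition(tokens: list[str]) -> None:
    """Validate the leaflet grammar (``-u NAME:N``/``-l NAME:N`` pairs).

    The tokens are forwarded opaquely to the membrane builder, but a custom
    composition must specify both leaflets.
    """
    if not tokens:
        return  # default: pure POPC bilayer
    upper = any(t == "-u" for t in tokens)
    lower = any(t == "-l" for t in tokens)
    if not (upper and lower):
        raise UsageError("custom membrane composition must specify both "
                         "leaflets (-u and -l)")


def plan_mempro(input_pdb: str, composition: list[str] | None = None,
                conc: float | None = None,
                extra_args: list[str] | None = None) -> list[str]:
    check_membrane_composition(composition or [])
    args = ["-f", input_pdb]
    args.extend(composition or [])
    if conc is not None:
        args.extend(["-conc", str(conc)])
    args.extend(extra_args or [])
    return args


def plan_cg2at(cg_pdb: str, extra_args: list[str] | None = None) -> list[str]:
    return ["-c", cg_pdb] + list(extra_args or [])


def require_mempro_env() -> dict[str, str]:
    """Read the environment the embedding pipeline needs; error if missing."""
    missing = [v for v in MEMPRO_ENV_VARS if not os.environ.get(v)]
    if missing:
        raise ExternalToolError(
            f"membrane embedding requires environment variables {missing}")
    return {v: os.environ[v] for v in MEMPRO_ENV_VARS}


def default_runner(tool: str, argv: list[str]) -> bool:
    """Run an external tool if present; return False (skip) when absent."""
    exe = shutil.which(tool)
    if exe is None:
        logger.warning("external tool %r not found; planned invocation "
                       "skipped: %s", tool, " ".join(argv))
        return False
    import subprocess

    result = subprocess.run([exe] + list(argv))
    if result.returncode != 0:
        raise ExternalToolError(f"{tool} exited with {result.returncode}")
    return True
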