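"""Validation diagnostics shared by the three model layers."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Diagnostic", "ModelError"]


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding.

    rule     machine-readable rule name, e.g. ``multiple-initial-regime``
    element  path to the offending element, e.g. ``LIF/Regime[refractory]``
    message  human-readable explanation
    severity ``error`` or ``warning``
    """

    rule: str
    element: str
    message: str
    severity: str = "error"

    def __str__(self) -> str:
        return f"[{self.severity}] {self.rule} at {self.element}: {self.message}"


class ModelError(ValueError):
    """Raised when an operation refuses to proceed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: list[Diagnostic] | None = None):
        self.diagnostics = diagnostics or []
        detail = "\n".join(str(d) for d in self.diagnostics)
        super().__init__(message + ("\n" + detail if detail else ""))
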