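"""Plain-text SEM model grammar and the structured model specification.

Grammar (one statement per line, ``#`` comments allowed)::

    latent <name> = <indicator> [+ <indicator> ...]   # measurement model
    path <from> -> <to>                               # structural / covariate path
    covary <a> <b>                                    # free covariance
    fix <from> -> <to> = <value>                      # fix a loading or path
    fix var(<name>) = <value>                         # fix a variance
    fix cov(<a>,<b>) = <value>                        # fix a covariance
    std <latent>                                      # identify by unit variance

Internals follow the all-y convention: observed indicators ``y`` load on
latents ``eta`` (``y = Lambda eta + eps``), latents regress on each other
and on exogenous observed covariates ``x`` (``eta = B eta + Gamma x +
zeta``).  An observed variable that receives a path (e.g. the trait) is
promoted to a phantom latent with a unit loading and zero measurement
residual, so its disturbance plays the role of a regression residual.

Identification default: the first listed indicator of each latent is the
marker (loading fixed to 1); ``std`` switches that latent to unit
variance instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["Param", "SemModelSpec", "parse_model_spec"]

_PHANTOM = "~"  # prefix for phantom latents backing observed endogenous variables


@dataclass(frozen=True)
class Param:
    """One entry of a model matrix.

    ``matrix`` is one of lam/beta/gam/theta/psi/phi; ``pclass`` is the
    reporting class (loading, path, residual, disturbance, covariance,
    x_cov); variance parameters are optimized on the log scale.
    """

    label: str
    matrix: str
    i: int
    j: int
    pclass: str
    free: bool
    value: float | None = None  # fixed value when not free
    log_scale: bool = False


@dataclass
class SemModelSpec:
    latents: dict[str, list[str]] = field(default_factory=dict)
    paths: list[tuple[str, str]] = field(default_factory=list)
    covary_pairs: list[tuple[str, str]] = field(default_factory=list)
    fixes: dict[str, float] = field(default_factory=dict)
    std_latents: set[str] = field(default_factory=set)

    # ----- derived structure -------------------------------------------------

    def _validate_names(self) -> None:
        inds = [i for v in self.latents.values() for i in v]
        clash = set(self.latents) & set(inds)
        if clash:
            raise ValueError(f"names used as both latent and indicator: {sorted(clash)}")
        mentioned = set(self.latents) | set(inds)
        for a, b in self.paths:
            mentioned.update((a, b))
        for a, b in self.covary_pairs:
            if a not in mentioned or b not in mentioned:
                missing = [v for v in (a, b) if v not in mentioned]
                raise ValueError(f"covary references unknown variables: {missing}")
        unknown_std = self.std_latents - set(self.latents)
        if unknown_std:
            raise ValueError(f"std applied to non-latent names: {sorted(unknown_std)}")

    @property
    def indicator_vars(self) -> list[str]:
        seen: dict[str, None] = {}
        for inds in self.latents.values():
            for v in inds:
                seen.setdefault(v, None)
        return list(seen)

    @property
    def observed_endogenous(self) -> list[str]:
        """Observed path targets (e.g. the trait): get phantom latents."""
        inds = set(self.indicator_vars)
        out: dict[str, None] = {}
        for _, dst in self.paths:
            if dst not in self.latents and dst not in inds:
                out.setdefault(dst, None)
        return list(out)

    @property
    def y_vars(self) -> list[str]:
        return self.indicator_vars + self.observed_endogenous

    @property
    def x_vars(self) -> list[str]:
        y = set(self.y_vars)
        lat = set(self.latents)
        out: dict[str, None] = {}
        for src, _ in self.paths:
            if src not in lat and src not in y:
                out.setdefault(src, None)
        return list(out)

    @property
    def all_latents(self) -> list[str]:
        return list(self.latents) + [_PHANTOM + v for v in self.observed_endogenous]

    @property
    def observed_vars(self) -> list[str]:
        return self.y_vars + self.x_vars

    def _latent_index(self, name: str) -> int:
        try:
            return self.all_latents.index(name)
        except ValueError:
            return self.all_latents.index(_PHANTOM + name)

    def _is_endogenous(self, latent: str) -> bool:
        if latent.startswith(_PHANTOM):
            return True
        base = latent
        for src, dst in self.paths:
            if dst == base:
                return True
        return False

    # ----- parameter table ---------------------------------------------------

    def parameters(self) -> list[Param]:
        """Enumerate every free and fixed parameter of the model.

        Raises if a fix targets a parameter the structure does not
        contain, or if a latent is left unidentified.
        """
        self._validate_names()
        y, x, lat = self.y_vars, self.x_vars, self.all_latents
        yi = {v: k for k, v in enumerate(y)}
        xi = {v: k for k, v in enumerate(x)}
        li = {v: k for k, v in enumerate(lat)}
        params: list[Param] = []
        fixes = dict(self.fixes)

        def take_fix(label: str) -> float | None:
            return fixes.pop(label, None)

        # measurement model
        for name, inds in self.latents.items():
            if not inds:
                raise ValueError(f"latent {name} has no indicators")
            for pos, ind in enumerate(inds):
                label = f"{name}->{ind}"
                fixed = take_fix(label)
                marker = pos == 0 and name not in self.std_latents
                if fixed is not None:
                    params.append(Param(label, "lam", yi[ind], li[name], "loading", False, fixed))
                elif marker:
                    params.append(Param(label, "lam", yi[ind], li[name], "loading", False, 1.0))
                else:
                    params.append(Param(label, "lam", yi[ind], li[name], "loading", True))
        for v in self.observed_endogenous:
            params.append(Param(f"{_PHANTOM}{v}->{v}", "lam", yi[v], li[_PHANTOM + v], "loading", False, 1.0))

        # structural and covariate paths
        for src, dst in self.paths:
            label = f"{src}->{dst}"
            fixed = take_fix(label)
            r = self._latent_index(dst)
            if src in li or src in self.observed_endogenous:
                c = self._latent_index(src)
                if r == c:
                    raise ValueError(f"self-loop path {label}")
                params.append(Param(label, "beta", r, c, "path", fixed is None, fixed))
            elif src in xi:
                params.append(Param(label, "gam", r, xi[src], "path", fixed is None, fixed))
            else:
                raise ValueError(f"path source {src!r} is an indicator; model it as a latent or covariate")

        # measurement residuals Theta
        phantom_y = set(self.observed_endogenous)
        for v in y:
            if v in phantom_y:
                continue  # measurement residual structurally zero; var(v) names the disturbance
            label = f"var({v})"
            fixed = take_fix(label)
            if fixed is not None:
                params.append(Param(label, "theta", yi[v], yi[v], "residual", False, fixed))
            else:
                params.append(Param(label, "theta", yi[v], yi[v], "residual", True, log_scale=True))

        # latent variances / disturbances Psi
        for name in lat:
            disp = name.lstrip(_PHANTOM)
            label = f"var({disp})" if name.startswith(_PHANTOM) else f"var({name})"
            fixed = take_fix(label)
            pclass = "disturbance"
            if fixed is not None:
                params.append(Param(label, "psi", li[name], li[name], pclass, False, fixed))
            elif not name.startswith(_PHANTOM) and name in self.std_latents and not self._is_endogenous(name):
                params.append(Param(label, "psi", li[name], li[name], pclass, False, 1.0))
            else:
                params.append(Param(label, "psi", li[name], li[name], pclass, True, log_scale=True))

        # covariances: defaults (saturated among exogenous latents) + declared
        pairs: dict[tuple[str, str], None] = {}
        exo = [v for v in self.latents if not self._is_endogenous(v)]
        for a_idx in range(len(exo)):
            for b_idx in range(a_idx + 1, len(exo)):
                pairs.setdefault((exo[a_idx], exo[b_idx]), None)
        for a, b in self.covary_pairs:
            pairs.setdefault((a, b), None)
        for a, b in pairs:
            label = f"cov({a},{b})"
            fixed = take_fix(label)
            if fixed is None:
                fixed = take_fix(f"cov({b},{a})")
            if a in li and b in li:
                params.append(Param(label, "psi", li[a], li[b], "covariance", fixed is None, fixed))
            elif a in yi and b in yi:
                params.append(Param(label, "theta", yi[a], yi[b], "residual", fixed is None, fixed))
            elif a in xi and b in xi:
                pass  # Phi is saturated below
            else:
                raise ValueError(f"covary pair ({a}, {b}) mixes variable kinds")

        # exogenous covariate moments Phi (saturated)
        for a_idx in range(len(x)):
            for b_idx in range(a_idx, len(x)):
                a, b = x[a_idx], x[b_idx]
                if a == b:
                    label = f"var({a})"
                    fixed = take_fix(label)
                    params.append(
                        Param(label, "phi", a_idx, a_idx, "x_cov", fixed is None, fixed, log_scale=fixed is None)
                    )
                else:
                    label = f"cov({a},{b})"
                    fixed = take_fix(label)
                    params.append(Param(label, "phi", a_idx, b_idx, "x_cov", fixed is None, fixed))

        if fixes:
            raise ValueError(f"fix statements match no model parameter: {sorted(fixes)}")
        labels = [p.label for p in params]
        dup = {l for l in labels if labels.count(l) > 1}
        if dup:
            raise ValueError(f"duplicate parameters: {sorted(dup)}")
        return params

    @property
    def n_free(self) -> int:
        return sum(p.free for p in self.parameters())

    # ----- text round-trip ---------------------------------------------------

    def to_text(self) -> str:
        lines = []
        for name, inds in self.latents.items():
            lines.append(f"latent {name} = " + " + ".join(inds))
        for name in sorted(self.std_latents):
            lines.append(f"std {name}")
        for src, dst in self.paths:
            lines.append(f"path {src} -> {dst}")
        for a, b in self.covary_pairs:
            lines.append(f"covary {a} {b}")
        for label, value in self.fixes.items():
            m = re.fullmatch(r"(\S+)->(\S+)", label)
            if m:
                lines.append(f"fix {m.group(1)} -> {m.group(2)} = {value:g}")
            else:
                lines.append(f"fix {label} = {value:g}")
        return "\n".join(lines) + "\n"


def parse_model_spec(text: str) -> SemModelSpec:
    """Parse the plain-text grammar into a validated :class:`SemModelSpec`."""
    spec = SemModelSpec()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            _parse_line(line, spec)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    if not spec.latents and not spec.paths:
        raise ValueError("empty model: no latent or path statements")
    spec._validate_names()
    spec.parameters()  # surface structural errors early
    return spec


def _parse_line(line: str, spec: SemModelSpec) -> None:
    m = re.fullmatch(r"latent\s+(\S+)\s*=\s*(.+)", line)
    if m:
        name, rhs = m.group(1), m.group(2)
        inds = [t.strip() for t in rhs.split("+")]
        if name in spec.latents:
            raise ValueError(f"duplicate latent declaration {name}")
        if any(not i for i in inds) or len(inds) != len(set(inds)):
            raise ValueError(f"bad indicator list for latent {name}")
        spec.latents[name] = inds
        return
    m = re.fullmatch(r"path\s+(\S+)\s*->\s*(\S+)", line)
    if m:
        edge = (m.group(1), m.group(2))
        if edge in spec.paths:
            raise ValueError(f"duplicate path {edge[0]} -> {edge[1]}")
        spec.paths.append(edge)
        return
    m = re.fullmatch(r"covary\s+(\S+)\s+(\S+)", line)
    if m:
        pair = (m.group(1), m.group(2))
        if pair in spec.covary_pairs or pair[::-1] in spec.covary_pairs:
            raise ValueError(f"duplicate covary {pair}")
        spec.covary_pairs.append(pair)
        return
    m = re.fullmatch(r"fix\s+(\S+)\s*->\s*(\S+)\s*=\s*([-+0-9.eE]+)", line)
    if m:
        spec.fixes[f"{m.group(1)}->{m.group(2)}"] = float(m.group(3))
        return
    m = re.fullmatch(r"fix\s+((?:var|cov)\([^)]+\))\s*=\s*([-+0-9.eE]+)", line)
    if m:
        spec.fixes[m.group(1).replace(" ", "")] = float(m.group(2))
        return
    m = re.fullmatch(r"std\s+(\S+)", line)
    if m:
        spec.std_latents.add(m.group(1))
        return
    raise ValueError(f"unrecognized statement: {line!r}")
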