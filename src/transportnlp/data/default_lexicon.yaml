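# Default transportation-insecurity lexicon.
#
# Transport terms name a means of getting to an appointment; need terms are
# the cue words whose co-occurrence with a transport term (within one
# sentence, bounded character gap, either order) flags a mention.
#
# "transit" is deliberately absent from the transport terms: it collides with
# the transit phase of fluorescein angiography. Driving terms are kept but a
# default-on exclusion rule suppresses them in visual-function contexts
# (cataract/glare/night-vision complaints), where "difficulty driving"
# describes eyesight, not access to care.
#
# provenance: "validated" = part of the clinically reviewed term set;
# "inferred" = added so documented matched expressions such as "no ride" and
# "no transportation" are reproducible.
transport_terms:
  - {label: transportation, pattern: "transportation", enabled: true, provenance: validated}
  - {label: ride, pattern: "ride", enabled: true, provenance: validated}
  - {label: driving, pattern: "driv(e|ing)", enabled: true, provenance: validated}
need_terms:
  - {label: work-on, pattern: "work on", enabled: true, provenance: validated}
  - {label: options, pattern: "option(s)", enabled: true, provenance: validated}
  - {label: issues, pattern: "issue(s)", enabled: true, provenance: validated}
  - {label: due-to, pattern: "due to", enabled: true, provenance: validated}
  - {label: assist, pattern: "assist(ance)?", enabled: true, provenance: validated}
  - {label: access, pattern: "access", enabled: true, provenance: validated}
  - {label: adequate, pattern: "adequate", enabled: true, provenance: validated}
  - {label: discuss, pattern: "discuss(ed|es|ing)", enabled: true, provenance: validated}
  - {label: able, pattern: "(un)?able", enabled: true, provenance: validated}
  - {label: accommodation, pattern: "accommodation", enabled: true, provenance: validated}
  - {label: support, pattern: "support", enabled: true, provenance: validated}
  - {label: agree, pattern: "agree(s)?", enabled: true, provenance: validated}
  - {label: apply, pattern: "appl(y|ies)", enabled: true, provenance: validated}
  - {label: arrange, pattern: "arrang(es|ed|e|ing)?", enabled: true, provenance: validated}
  - {label: need, pattern: "need(s)", enabled: true, provenance: validated}
  - {label: blame, pattern: "blam(e|es|ing)", enabled: true, provenance: validated}
  - {label: find, pattern: "find(s|ing)", enabled: true, provenance: validated}
  - {label: connect, pattern: "connect(ing|ed)?", enabled: true, provenance: validated}
  - {label: could-not, pattern: "could(n['’]t| not)", enabled: true, provenance: validated}
  - {label: did-not, pattern: "did(n['’]t|not)", enabled: true, provenance: validated}
  - {label: difficulty, pattern: "difficult(y|ies)?", enabled: true, provenance: validated}
  - {label: get, pattern: "get(ting)?", enabled: true, provenance: validated}
  - {label: help, pattern: "help", enabled: true, provenance: validated}
  - {label: does-not, pattern: "does(n['’]t| not)", enabled: true, provenance: validated}
  - {label: lack, pattern: "lack(s|ing)?", enabled: true, provenance: validated}
  - {label: easier, pattern: "easier", enabled: true, provenance: validated}
  - {label: ems, pattern: "EMS", enabled: true, provenance: validated}
  - {label: investigate, pattern: "investigate", enabled: true, provenance: validated}
  - {label: use, pattern: "us(es|e|ing)", enabled: true, provenance: validated}
  - {label: depend, pattern: "depend(s|ing)?", enabled: true, provenance: validated}
  - {label: organize, pattern: "organiz(es|e|ing)", enabled: true, provenance: validated}
  - {label: coordination, pattern: "coordination", enabled: true, provenance: validated}
  - {label: possible, pattern: "possible", enabled: true, provenance: validated}
  - {label: resources, pattern: "resources", enabled: true, provenance: validated}
  - {label: limit, pattern: "limit(s|ations)?", enabled: true, provenance: validated}
  - {label: convenience, pattern: "convenience", enabled: true, provenance: validated}
  - {label: trouble, pattern: "trouble(s)?", enabled: true, provenance: validated}
  - {label: secure, pattern: "secur(es|e|ing)", enabled: true, provenance: validated}
  - {label: concern, pattern: "concern(s)?", enabled: true, provenance: validated}
  - {label: regarding, pattern: "regarding", enabled: true, provenance: validated}
  - {label: rely, pattern: "reli(es|able|ant)", enabled: true, provenance: validated}
  - {label: time-allowance, pattern: "time allowance", enabled: true, provenance: validated}
  - {label: problem, pattern: "problem(s)?", enabled: true, provenance: validated}
  - {label: challenge, pattern: "challeng(es|e|ing)", enabled: true, provenance: validated}
  - {label: purpose, pattern: "purpose(s)?", enabled: true, provenance: validated}
  - {label: offer, pattern: "offer(s|ed)", enabled: true, provenance: validated}
  - {label: provide, pattern: "provid(es|ed|e|ing)", enabled: true, provenance: validated}
  - {label: "no", pattern: "no", enabled: true, provenance: inferred}
exclusion_rules:
  - label: driving-visual-function
    trigger: "driv(e|ing)"
    context: "glare|night|vision|blurr|cataract|see(ing)?"
    enabled: true
    provenance: validated
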