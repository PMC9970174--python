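term,category,source
well-being,rehab,quoted in study text
CNAME will,rehab,quoted in study text
metabolic monitoring,rehab,quoted in study text
strengths,rehab,fixture
independence,rehab,fixture
enduring,person,quoted in study text
CNAME was,person,quoted in study text; fixture category assignment
CNAME had,person,quoted in study text; fixture category assignment
hopes,person,fixture
chronic,pejorative,quoted in study text; fixture category assignment
not been able,pejorative,quoted in study text; fixture category assignment
is not able,pejorative,quoted in study text; fixture category assignment
non-compliant,pejorative,fixture
uncooperative,pejorative,fixture
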