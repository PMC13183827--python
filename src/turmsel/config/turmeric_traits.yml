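# Trait roster for the turmeric half-sib trial: 17 vegetative, rhizome,
# yield and quality traits. `direction` is the desired direction under
# selection; `ideotype` is a closed window [lo, hi] used for ideotype
# counting (null where no window is defined).
PH:  {label: "Plant height",                 units: "cm",   direction: increase, ideotype: [80, 110]}
NT:  {label: "Number of tillers per plant",  units: "count", direction: increase, ideotype: [4, 6]}
NL:  {label: "Number of leaves per shoot",   units: "count", direction: increase, ideotype: null}
LL:  {label: "Leaf length",                  units: "cm",   direction: increase, ideotype: null}
LW:  {label: "Leaf width",                   units: "cm",   direction: increase, ideotype: null}
LA:  {label: "Leaf area",                    units: "cm2",  direction: increase, ideotype: null}
PL:  {label: "Petiole length",               units: "cm",   direction: increase, ideotype: null}
CG:  {label: "Collar girth",                 units: "cm",   direction: increase, ideotype: null}
NMR: {label: "Number of mother rhizomes",    units: "count", direction: increase, ideotype: null}
WMR: {label: "Weight of mother rhizomes",    units: "kg",   direction: increase, ideotype: null}
NPR: {label: "Number of primary rhizomes",   units: "count", direction: increase, ideotype: null}
LPR: {label: "Length of primary rhizome",    units: "cm",   direction: increase, ideotype: null}
IL:  {label: "Internodal length",            units: "cm",   direction: increase, ideotype: null}
GPR: {label: "Girth of primary rhizome",     units: "cm",   direction: increase, ideotype: null}
WPR: {label: "Weight of primary rhizomes",   units: "kg",   direction: increase, ideotype: null}
TY:  {label: "Total yield per plant",        units: "kg",   direction: increase, ideotype: [0.60, .inf]}
DR:  {label: "Dry recovery",                 units: "%",    direction: increase, ideotype: [24, .inf]}
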