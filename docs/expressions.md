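# Expression grammar

Every user-supplied formula — diffusivities, kinetics, boundary data,
domain indicators, initial conditions, views — is a plain-text expression
in a small calculator language, parsed with conventional precedence and
evaluated elementwise over grid-shaped arrays.

## EBNF

```ebnf
expr    = term , { ( "+" | "-" ) , term } ;
term    = factor , { ( "*" | "/" ) , factor } ;
factor  = "-" , factor
        | "+" , factor
        | power ;
power   = atom , [ "^" , factor ] ;          (* right-associative *)
atom    = number
        | symbol
        | function , "(" , expr , { "," , expr } , ")"
        | "(" , expr , ")" ;
number  = digits , [ "." , [ digits ] ] , [ exponent ]
        | "." , digits , [ exponent ] ;
exponent = ( "e" | "E" ) , [ "+" | "-" ] , digits ;
symbol  = letter-or-underscore , { letter-or-digit-or-underscore } ;
```

Notes:

* `^` is exponentiation, right-associative, binding tighter than unary
  minus: `-2^2 = -4`, `2^3^2 = 512`, `2^-1 = 0.5`.
* Symbols are case-sensitive.

## Symbols

Which symbols resolve depends on context (validation reports any symbol
that is out of place, by name):

| symbol                  | meaning                            | available in |
|-------------------------|------------------------------------|--------------|
| species names           | current field values               | everywhere except indicators/ICs |
| `x`, `y`                | node coordinates                   | everywhere   |
| `t`                     | model time                         | all but indicators/ICs |
| parameter names         | values from `params`               | everywhere   |
| `pi`                    | constant                           | everywhere   |
| `rand`                  | seeded uniform(0,1) noise field    | initial conditions only |
| `I_S(x,y)`, `I_T(x,y)`  | image samplers (if configured)     | everywhere   |
| derivative tokens       | see below                          | kinetics, algebraic defs, views |

## Derivative tokens

For a species `u`: `u_x`, `u_y` (central first differences), `u_xx`,
`u_yy` (second differences), and the one-sided upwind variants `u_x_b`,
`u_x_f`, `u_y_b`, `u_y_f` (backward/forward).  There are no mixed tokens
(`u_xy` is rejected with a dedicated diagnostic).  Diffusivity entries and
boundary data may not contain derivative tokens.

## Functions

`sin cos tan exp log sqrt abs tanh` (one argument), `min max` (two or
more), `heaviside` with the convention `heaviside(0) = 1`.

## Error behaviour

Parsing reports syntax errors with a character position and unknown
symbols/functions by name.  Evaluation is pure (same context, bit-identical
result) and never raises on numeric trouble: division by zero, `log` of a
non-positive value, overflow all yield `inf`/`nan`, which the simulator's
blow-up detector converts into a "solution blew up at t=…" error.
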