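{
 "intro": [
  "paciente de {age} anos con diabetes mellitus tipo dos",
  "{age} year old patient with type two diabetes",
  "paciente {age} anos en control de diabetes"
 ],
 "condition": [
  "antecedente de {e}",
  "patient with {e}",
  "dx {e}",
  "con {e}"
 ],
 "drug": [
  "manejo con {e} {dose}",
  "{e} {dose}",
  "on handling with {e} {dose}",
  "recibe {e} {dose}",
  "formula {e} {dose}"
 ],
 "doses": [
  "20x1",
  "50 mg dia",
  "100x1 noche",
  "10 mg cada 12 h",
  "850 mg comidas",
  "25 unidades noche"
 ],
 "adherence": [
  "{e}",
  "nota {e}",
  "valoracion {e}"
 ],
 "recommendation": [
  "{e}",
  "refuerzo {e}",
  "indicacion {e}"
 ],
 "guideline_marker": [
  "{e}",
  "ajuste manejo {e}"
 ],
 "closing": [
  "control en tres meses",
  "proxima cita en un mes",
  "next appointment in three months"
 ],
 "distractors": [
  "paciente estable",
  "signos vitales normales",
  "tolerancia oral conservada",
  "explican signos alarma",
  "asiste acompanado",
  "revision sistemas normal",
  "examen fisico normal"
 ]
}
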